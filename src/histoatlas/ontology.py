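"""Hierarchical brain-region ontology: data model, validation, and I/O.

The ontology is a tree of named brain structures. Each node carries a
positive integer id (0 is reserved for image background), a short acronym,
a display color, and a ``level`` between 0 and 4. Level 0 holds the root
divisions (gray matter, white matter, ventricular system); deeper levels
subdivide them down to layers and nuclei. A node's level may jump more than
one tier below its parent: anatomical groupings do not all live at the same
depth, but queries such as "all major structures" address one level.

On disk the node set lives in an ITK-SNAP style ``.label`` text file
(columns ``ID R G B A VIS MSH "NAME"``); the tree topology, acronyms, and
the annotation level live in a JSON sidecar next to it, because the
``.label`` dialect has no parent column.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

__all__ = [
    "OntologyNode",
    "Ontology",
    "OntologyError",
    "load_label_file",
    "write_label_file",
    "count_nodes_at",
    "aggregate_to_level",
    "default_ontology",
]

MAX_LEVEL = 4


class OntologyError(ValueError):
    """Raised when an ontology violates a structural invariant."""


@dataclass(frozen=True)
class OntologyNode:
    """One named brain structure.

    Parameters
    ----------
    id : positive integer, unique in the tree; 0 is reserved for background.
    acronym : short display string, e.g. ``"HPF"``.
    name : full structure name.
    color : RGB triple, each channel in 0..255.
    parent_id : id of the parent node, or ``None`` for a root division.
    level : depth tier 0..4; children must sit strictly below their parent.
    """

    id: int
    acronym: str
    name: str
    color: Tuple[int, int, int]
    parent_id: Optional[int] = None
    level: int = 0

    def __post_init__(self) -> None:
        if self.id <= 0:
            raise OntologyError(f"node id must be positive, got {self.id}")
        if not (0 <= self.level <= MAX_LEVEL):
            raise OntologyError(
                f"node {self.id}: level {self.level} outside 0..{MAX_LEVEL}"
            )
        color = tuple(int(c) for c in self.color)
        if len(color) != 3 or any(c < 0 or c > 255 for c in color):
            raise OntologyError(f"node {self.id}: bad color {self.color!r}")
        object.__setattr__(self, "color", color)


class Ontology:
    """A validated tree of :class:`OntologyNode`.

    The root is virtual: nodes with ``parent_id is None`` are the root
    divisions. ``annotation_level_ids`` lists the ids used for coarse
    manual annotation (the "major structures").
    """

    def __init__(
        self,
        nodes: Iterable[OntologyNode],
        annotation_level_ids: Sequence[int] = (),
    ) -> None:
        self.nodes: Dict[int, OntologyNode] = {}
        for node in nodes:
            if node.id in self.nodes:
                raise OntologyError(f"duplicate id {node.id}")
            self.nodes[node.id] = node
        self.annotation_level_ids: List[int] = list(annotation_level_ids)
        self.validate()

    # -- structure queries -------------------------------------------------

    def __len__(self) -> int:
        return len(self.nodes)

    def __contains__(self, region_id: int) -> bool:
        return region_id in self.nodes

    def __getitem__(self, region_id: int) -> OntologyNode:
        return self.nodes[region_id]

    def children(self, region_id: Optional[int]) -> List[OntologyNode]:
        return [n for n in self.nodes.values() if n.parent_id == region_id]

    def roots(self) -> List[OntologyNode]:
        return self.children(None)

    def leaves(self) -> List[OntologyNode]:
        parent_ids = {n.parent_id for n in self.nodes.values()}
        return [n for n in self.nodes.values() if n.id not in parent_ids]

    def ancestors(self, region_id: int) -> List[OntologyNode]:
        """Path from the node's parent up to its root division."""
        out = []
        node = self.nodes[region_id]
        while node.parent_id is not None:
            node = self.nodes[node.parent_id]
            out.append(node)
        return out

    def descendants(self, region_id: int) -> List[OntologyNode]:
        out: List[OntologyNode] = []
        stack = [region_id]
        while stack:
            for child in self.children(stack.pop()):
                out.append(child)
                stack.append(child.id)
        return out

    def descendant_leaves(self, region_id: int) -> List[OntologyNode]:
        node = self.nodes[region_id]
        desc = self.descendants(region_id)
        if not desc:
            return [node]
        leaf_ids = {n.id for n in self.leaves()}
        return [n for n in desc if n.id in leaf_ids]

    def is_ancestor(self, ancestor_id: int, node_id: int) -> bool:
        return any(a.id == ancestor_id for a in self.ancestors(node_id))

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        for node in self.nodes.values():
            if node.parent_id is not None:
                if node.parent_id not in self.nodes:
                    raise OntologyError(
                        f"node {node.id}: parent {node.parent_id} does not exist"
                    )
                parent = self.nodes[node.parent_id]
                if node.level <= parent.level:
                    raise OntologyError(
                        f"node {node.id} (level {node.level}) must sit below "
                        f"parent {parent.id} (level {parent.level})"
                    )
        # cycle check: every node must reach a root in <= len(nodes) hops
        for node in self.nodes.values():
            seen = set()
            cur: Optional[int] = node.id
            while cur is not None:
                if cur in seen:
                    raise OntologyError(f"cycle through node {cur}")
                seen.add(cur)
                cur = self.nodes[cur].parent_id
        # color collisions permitted only along one root-to-leaf path
        by_color: Dict[Tuple[int, int, int], List[int]] = {}
        for node in self.nodes.values():
            by_color.setdefault(node.color, []).append(node.id)
        for color, ids in by_color.items():
            if len(ids) < 2:
                continue
            for i, a in enumerate(ids):
                for b in ids[i + 1 :]:
                    if not (self.is_ancestor(a, b) or self.is_ancestor(b, a)):
                        raise OntologyError(
                            f"nodes {a} and {b} share color {color} but are "
                            "not on one root-to-leaf path"
                        )
        for rid in self.annotation_level_ids:
            if rid not in self.nodes:
                raise OntologyError(f"annotation level id {rid} does not exist")


# -- operations -----------------------------------------------------------


def count_nodes_at(ontology: Ontology, level: int) -> int:
    """Number of ontology nodes stored at depth tier ``level``."""
    if not (0 <= level <= MAX_LEVEL):
        raise OntologyError(f"level {level} outside 0..{MAX_LEVEL}")
    return sum(1 for n in ontology.nodes.values() if n.level == level)


def aggregate_to_level(
    leaf_values: Mapping[int, float], ontology: Ontology, level: int
) -> Dict[int, float]:
    """Sum per-leaf values onto the tree cut at ``level``.

    Each leaf contributes to its deepest ancestor-or-self whose level is
    ``<= level``; because leaves live at heterogeneous depths, output keys
    may carry levels shallower than ``level``. Total mass is conserved for
    every choice of ``level``.
    """
    if not (0 <= level <= MAX_LEVEL):
        raise OntologyError(f"level {level} outside 0..{MAX_LEVEL}")
    leaf_ids = {n.id for n in ontology.leaves()}
    out: Dict[int, float] = {}
    for leaf_id, value in leaf_values.items():
        if leaf_id not in leaf_ids:
            raise OntologyError(f"id {leaf_id} is not a leaf of the ontology")
        node = ontology.nodes[leaf_id]
        target = None
        for cand in [node] + ontology.ancestors(leaf_id):
            if cand.level <= level:
                target = cand
                break
        if target is None:  # leaf above the cut keeps its own bucket
            target = node
        out[target.id] = out.get(target.id, 0.0) + float(value)
    return out


# -- .label / sidecar I/O --------------------------------------------------

_LABEL_LINE = re.compile(
    r"^\s*(\d+)\s+(\d+)\s+(\d+)\s+(\d+)\s+([\d.]+)\s+(\d+)\s+(\d+)\s+\"(.*)\"\s*$"
)

_LABEL_HEADER = """\
################################################
# Anatomical structure label description file
# Columns: ID R G B A VIS MSH "NAME"
################################################
"""


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def load_label_file(path: str | Path) -> Ontology:
    """Read an ITK-SNAP style ``.label`` file (plus JSON sidecar if present).

    Without a sidecar the tree is flat: every labelled structure becomes a
    level-0 root division and its acronym is derived from the name.
    """
    path = Path(path)
    rows: Dict[int, Tuple[Tuple[int, int, int], str]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        m = _LABEL_LINE.match(line)
        if m is None:
            raise OntologyError(f"{path}:{lineno}: unparseable label line: {line!r}")
        rid = int(m.group(1))
        if rid == 0:  # background row, ignored
            continue
        if rid in rows:
            raise OntologyError(f"duplicate id {rid} ({path}:{lineno})")
        color = (int(m.group(2)), int(m.group(3)), int(m.group(4)))
        rows[rid] = (color, m.group(8))

    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        info = {int(n["id"]): n for n in meta["nodes"]}
        nodes = []
        for rid, (color, name) in rows.items():
            n = info.get(rid, {})
            nodes.append(
                OntologyNode(
                    id=rid,
                    acronym=str(n.get("acronym", name[:8])),
                    name=name,
                    color=color,
                    parent_id=n.get("parent_id"),
                    level=int(n.get("level", 0)),
                )
            )
        ann = [int(i) for i in meta.get("annotation_level_ids", [])]
        return Ontology(nodes, annotation_level_ids=ann)
    nodes = [
        OntologyNode(id=rid, acronym=name[:8], name=name, color=color)
        for rid, (color, name) in rows.items()
    ]
    return Ontology(nodes)


def write_label_file(ontology: Ontology, path: str | Path) -> None:
    """Write the ``.label`` file and its JSON hierarchy sidecar."""
    path = Path(path)
    lines = [_LABEL_HEADER]
    lines.append('    0     0    0    0        0  0  0    "Clear Label"\n')
    for rid in sorted(ontology.nodes):
        n = ontology.nodes[rid]
        r, g, b = n.color
        lines.append(f'{rid:5d} {r:5d} {g:4d} {b:4d}        1  1  1    "{n.name}"\n')
    path.write_text("".join(lines))
    meta = {
        "annotation_level_ids": list(ontology.annotation_level_ids),
        "nodes": [
            {
                "id": n.id,
                "parent_id": n.parent_id,
                "level": n.level,
                "acronym": n.acronym,
            }
            for n in ontology.nodes.values()
        ],
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


# -- packaged default tree -------------------------------------------------


def default_ontology() -> Ontology:
    """The packaged mouse-lemur-style region tree.

    Root divisions (level 0) split into gray matter, white matter, and the
    ventricular system. The 13 major structures used for coarse annotation
    all carry level 2: nine cerebral/brainstem subdivisions plus cerebellum,
    fiber tracts, and ventricular system (which hang directly off their
    divisions). The basal ganglia form a functional level-3 grouping under
    gray matter holding the seven motor-circuit nuclei as level-4 leaves;
    the hippocampal formation carries its five named subfields.
    """

    def n(rid, acr, name, color, parent, level):
        return OntologyNode(rid, acr, name, color, parent, level)

    nodes = [
        # level 0: root divisions
        n(1, "GM", "Gray matter", (191, 218, 227), None, 0),
        n(2, "WM", "White matter", (204, 204, 204), None, 0),
        n(3, "VSd", "Ventricular division", (170, 170, 170), None, 0),
        # level 1
        n(4, "CH", "Cerebrum", (176, 240, 255), 1, 1),
        n(5, "BS", "Brain stem", (255, 179, 217), 1, 1),
        # level 2: the 13 major structures
        n(10, "NCX", "Neocortex", (112, 255, 113), 4, 2),
        n(11, "HPF", "Hippocampal formation", (126, 208, 75), 4, 2),
        n(12, "OCX", "Other cortical regions", (33, 152, 102), 4, 2),
        n(13, "STR", "Striatum", (152, 214, 249), 4, 2),
        n(14, "PAL", "Pallidum", (133, 153, 204), 4, 2),
        n(15, "TH", "Thalamus", (255, 112, 128), 5, 2),
        n(16, "HY", "Hypothalamus", (230, 68, 56), 5, 2),
        n(17, "MB", "Midbrain", (255, 100, 255), 5, 2),
        n(18, "P", "Pons", (255, 155, 136), 5, 2),
        n(19, "MY", "Medulla", (255, 155, 205), 5, 2),
        n(20, "CB", "Cerebellum", (240, 240, 128), 1, 2),
        n(21, "ft", "Fiber tracts", (170, 170, 169), 2, 2),
        n(22, "VS", "Ventricular system", (128, 128, 128), 3, 2),
        # hippocampal subfields (level 3 under HPF)
        n(30, "CA", "Ammon's horn", (102, 168, 61), 11, 3),
        n(31, "DG", "Dentate gyrus", (126, 208, 117), 11, 3),
        n(32, "S", "Subiculum", (79, 194, 68), 11, 3),
        n(33, "PrS", "Pre/para-subiculum", (89, 179, 99), 11, 3),
        n(34, "Ent", "Entorhinal cortex", (50, 184, 37), 11, 3),
        # visual cortical areas (level 3 under NCX)
        n(40, "V1", "Primary visual cortex", (8, 133, 140), 10, 3),
        n(41, "V2", "Secondary visual cortex", (0, 159, 172), 10, 3),
        n(42, "V1-4a", "Primary visual cortex layer IVa", (46, 155, 160), 40, 4),
        n(43, "V1-4b", "Primary visual cortex layer IVb", (20, 143, 149), 40, 4),
        # basal ganglia: functional grouping, seven motor-circuit nuclei
        n(50, "BG", "Basal ganglia", (133, 183, 219), 1, 3),
        n(51, "Cd", "Caudate nucleus", (152, 214, 248), 50, 4),
        n(52, "Pu", "Putamen", (128, 205, 247), 50, 4),
        n(53, "GPe", "Globus pallidus externa", (133, 153, 203), 50, 4),
        n(54, "GPi", "Globus pallidus interna", (122, 142, 195), 50, 4),
        n(55, "STh", "Subthalamic nucleus", (227, 89, 82), 50, 4),
        n(56, "SNR", "Substantia nigra pars reticulata", (255, 90, 255), 50, 4),
        n(57, "SNC", "Substantia nigra pars compacta", (250, 100, 245), 50, 4),
    ]
    majors = [10, 11, 12, 13, 14, 15, 16, 17, 18, 19, 20, 21, 22]
    return Ontology(nodes, annotation_level_ids=majors)
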