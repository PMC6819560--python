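"""Haplogroup assignment from a reduced defining-variant tree.

A haplogroup is a maternal lineage defined by the variants accumulated on
its branch path. Assignment here scores, for every node, the fraction of
the node's root-path defining variants observed in the profile and returns
the best-scoring node (ties: deeper node, then lexicographically smallest
label). This is a deliberately reduced re-implementation sufficient for
stratification — not a full HaploGrep2 clone; private variants never
penalise a call and back-mutation path logic is limited to the pipeline's
exclusion lists.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field

from .errors import FormatError, ValidationError
from .variants import SubjectProfile, parse_variant_label


@dataclass(frozen=True)
class HaploNode:
    label: str
    parent: str | None
    defining_variants: frozenset[str] = field(default_factory=frozenset)


@dataclass(frozen=True)
class HaploCall:
    """Result of scoring a profile against the tree."""

    label: str
    score: float          # fraction of expected root-path variants observed
    missing: tuple[str, ...] = ()   # expected but absent
    private: tuple[str, ...] = ()   # observed but not on the winning path
    qc_flags: tuple[str, ...] = ()


class HaploTree:
    """Rooted acyclic tree of haplogroup nodes."""

    def __init__(self, nodes: list[HaploNode]):
        if not nodes:
            raise ValidationError("empty haplogroup tree")
        self.nodes = {n.label: n for n in nodes}
        if len(self.nodes) != len(nodes):
            raise ValidationError("duplicate haplogroup labels in tree")
        roots = [n for n in nodes if n.parent is None]
        if len(roots) != 1:
            raise ValidationError(f"tree needs exactly one root, got {len(roots)}")
        self.root = roots[0].label
        self._paths: dict[str, frozenset[str]] = {}
        self._depths: dict[str, int] = {}
        for label in self.nodes:
            self._resolve(label, seen=set())

    def _resolve(self, label: str, seen: set[str]) -> None:
        if label in self._paths:
            return
        if label in seen:
            raise ValidationError(f"cycle in haplogroup tree at {label}")
        seen.add(label)
        node = self.nodes[label]
        if node.parent is None:
            self._paths[label] = node.defining_variants
            self._depths[label] = 0
            return
        if node.parent not in self.nodes:
            raise ValidationError(
                f"node {label} references unknown parent {node.parent}")
        self._resolve(node.parent, seen)
        self._paths[label] = self._paths[node.parent] | node.defining_variants
        self._depths[label] = self._depths[node.parent] + 1

    def __contains__(self, label: str) -> bool:
        return label in self.nodes

    def labels(self) -> list[str]:
        return sorted(self.nodes)

    def path_variants(self, label: str) -> frozenset[str]:
        """Union of defining variants from the root to ``label``."""
        return self._paths[label]

    def depth(self, label: str) -> int:
        return self._depths[label]

    def descends_from(self, label: str, ancestor: str) -> bool:
        """True iff ``label`` equals ``ancestor`` or lies below it."""
        current: str | None = label
        while current is not None:
            if current == ancestor:
                return True
            current = self.nodes[current].parent
        return False


def load_tree(path: str | None = None) -> HaploTree:
    """Load a tree TSV (label, parent, comma-separated defining variants).

    With no path the packaged reduced tree is used.
    """
    if path is None:
        text = (importlib.resources.files("mitoburden.data")
                .joinpath("haplogroup_tree.tsv").read_text())
    else:
        with open(path) as handle:
            text = handle.read()
    nodes = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise FormatError(f"tree row needs 3 columns: {line!r}")
        label, parent, variants = fields
        labels = frozenset(
            parse_variant_label(tok).label
            for tok in variants.split(",")) if variants != "-" else frozenset()
        nodes.append(HaploNode(label, None if parent == "-" else parent,
                               labels))
    return HaploTree(nodes)


def assign_haplogroup(profile: SubjectProfile,
                      tree: HaploTree | None = None) -> HaploCall:
    """Score the profile against every node and return the best call.

    The score of a node is |observed ∩ root-path variants| / |root-path
    variants| (1.0 on an empty path — the reference node matches any
    profile vacuously). The winning node is the one explaining the most
    observed path variants, with ties broken by score, then depth, then
    lexicographically smallest label; an empty profile therefore maps to
    the reference lineage's node. Heteroplasmy fractions are ignored. A
    metadata haplogroup on the profile does not change the computed call;
    use :func:`effective_haplogroup` for the metadata-overriding
    behaviour.
    """
    tree = tree or load_tree()
    observed = {v.label for v in profile.variants}
    explained = {}
    scores = {}
    for label in tree.labels():
        path = tree.path_variants(label)
        explained[label] = len(observed & path)
        scores[label] = 1.0 if not path else explained[label] / len(path)
    # rank: most path variants explained, then score, then depth; a node
    # with an empty path (the reference lineage) matches vacuously, so a
    # score-only ranking would let it beat every imperfect real call
    best = max(explained[lb] for lb in tree.labels())
    tied = [lb for lb in tree.labels() if explained[lb] == best]
    top = max(scores[lb] for lb in tied)
    tied = [lb for lb in tied if scores[lb] == top]
    max_depth = max(tree.depth(lb) for lb in tied)
    winner = min(lb for lb in tied if tree.depth(lb) == max_depth)
    path = tree.path_variants(winner)
    return HaploCall(
        label=winner,
        score=top,
        missing=tuple(sorted(path - observed)),
        private=tuple(sorted(observed - path)),
    )


def effective_haplogroup(profile: SubjectProfile,
                         tree: HaploTree | None = None
                         ) -> tuple[str, HaploCall]:
    """Haplogroup used downstream: metadata label wins over the call.

    When both exist and disagree, the computed call is kept for QC with a
    ``metadata-overrides-call`` flag.
    """
    tree = tree or load_tree()
    call = assign_haplogroup(profile, tree)
    if profile.haplogroup is None:
        return call.label, call
    if profile.haplogroup != call.label:
        call = HaploCall(call.label, call.score, call.missing, call.private,
                         call.qc_flags + ("metadata-overrides-call",))
    return profile.haplogroup, call


def in_clade(label: str, clade: str, tree: HaploTree | None = None) -> bool:
    """True iff haplogroup ``label`` equals or descends from ``clade``.

    Descent is tree-based when the label is in the tree. For labels outside
    the reduced tree a guarded prefix rule is used: the remainder after the
    clade prefix must start with a digit or lowercase letter, so "J2a"
    matches clade "J" but the distinct haplogroup "JT" does not.
    """
    if tree is not None and label in tree and clade in tree:
        return tree.descends_from(label, clade)
    if label == clade:
        return True
    if label.startswith(clade):
        rest = label[len(clade):]
        return rest[0].isdigit() or rest[0].islower()
    return False


def in_jk_stratum(label: str, tree: HaploTree | None = None) -> bool:
    """True iff the haplogroup belongs to the J/K stratum.

    Unknown labels return False with a warning.
    """
    tree = tree or load_tree()
    if label in tree:
        return tree.descends_from(label, "J") or tree.descends_from(label, "K")
    if in_clade(label, "J") or in_clade(label, "K"):
        return True
    warnings.warn(f"unknown haplogroup label {label!r}; "
                  "treated as outside the J/K stratum")
    return False
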