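"""The fixed clinical decision pathway and its JSON tree dialect.

The validated bedside algorithm routes an awake patient through at most
three tests — arm lift, head lift, then swallowing (or eye opening on the
weak branch) — and ends in one of six terminal nodes.  Only the strongest
pathway (arm lift >= 5 s, head lift >= 5 s, swallowing 20 ml of water
without any hindrance; node 11) predicts absence of residual block; every
other terminal predicts a residual block at both the historical (TOFR <
0.7) and the modern (TOFR < 0.9) cut-off.

Trees are plain JSON so that both the shipped published pathway and trees
grown by :mod:`porc.cart` share one classifier, and so that users holding
the original figure can re-encode its interior exactly.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .cohort import SCORE_RANGES, PatientRecord, TestScores
from .errors import SpecValidationError

#: Terminal node ids of the published pathway.
PUBLISHED_TERMINALS = (3, 5, 6, 8, 10, 11)


@dataclass(frozen=True)
class SpecNode:
    id: int
    kind: str  # "internal" | "terminal"
    variable: Optional[str] = None
    threshold: Optional[float] = None
    left: Optional[int] = None
    right: Optional[int] = None
    block_lt_07: Optional[bool] = None
    block_lt_09: Optional[bool] = None
    tofr_band: Optional[str] = None
    n: Optional[int] = None
    mean_tofr: Optional[float] = None


@dataclass
class DecisionTreeSpec:
    """A binary decision tree over test scores, loaded from/saved to JSON."""

    nodes: dict[int, SpecNode]
    name: str = "unnamed"
    version: str = "1"
    root_id: int = 1

    # -- construction ------------------------------------------------------
    @classmethod
    def from_dict(cls, d: dict) -> "DecisionTreeSpec":
        nodes = {}
        for nd in d["nodes"]:
            node = SpecNode(
                id=int(nd["id"]),
                kind=nd["kind"],
                variable=nd.get("variable"),
                threshold=nd.get("threshold"),
                left=nd.get("left"),
                right=nd.get("right"),
                block_lt_07=nd.get("block_lt_07"),
                block_lt_09=nd.get("block_lt_09"),
                tofr_band=nd.get("tofr_band"),
                n=nd.get("n"),
                mean_tofr=nd.get("mean_tofr"),
            )
            if node.id in nodes:
                raise SpecValidationError(f"duplicate node id {node.id}")
            nodes[node.id] = node
        return cls(nodes=nodes, name=d.get("name", "unnamed"),
                   version=str(d.get("version", "1")))

    @classmethod
    def from_json(cls, path: str | Path) -> "DecisionTreeSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_dict(self) -> dict:
        nodes = []
        for i, nd in sorted(self.nodes.items()):
            d: dict = {"id": nd.id, "kind": nd.kind}
            for k in ("variable", "threshold", "left", "right", "block_lt_07",
                      "block_lt_09", "tofr_band", "n", "mean_tofr"):
                v = getattr(nd, k)
                if v is not None:
                    d[k] = v
            nodes.append(d)
        return {"name": self.name, "version": self.version, "nodes": nodes}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    # -- structure ---------------------------------------------------------
    def used_variables(self) -> list[str]:
        seen: list[str] = []
        for _, nd in sorted(self.nodes.items()):
            if nd.kind == "internal" and nd.variable not in seen:
                seen.append(nd.variable)  # type: ignore[arg-type]
        return seen

    def terminal_ids(self) -> list[int]:
        return [i for i, nd in sorted(self.nodes.items())
                if nd.kind == "terminal"]


def default_published_tree() -> DecisionTreeSpec:
    """The published six-pathway decision tree, from the packaged resource."""
    text = resources.files("porc.data").joinpath("published_tree.json").read_text()
    return DecisionTreeSpec.from_dict(json.loads(text))


# ---------------------------------------------------------------------------
# Classification


@dataclass(frozen=True)
class ClassificationResult:
    """Routing outcome for one patient.

    ``node_id`` is ``None`` when a required score was missing; then
    ``missing`` names the variable and the block predictions are undefined
    (never silently defaulted).
    """

    node_id: Optional[int]
    predicted_block_lt_07: Optional[bool]
    predicted_block_lt_09: Optional[bool]
    pathway: tuple[tuple[str, float, str], ...]
    missing: Optional[str] = None

    @property
    def classified(self) -> bool:
        return self.node_id is not None


def classify(scores: TestScores, spec: DecisionTreeSpec) -> ClassificationResult:
    """Route one score vector through the tree.

    Deterministic: comparisons use the ``score >= threshold -> right``
    convention (a patient holding the arm for exactly 5 s passes the 5 s
    cut).  A missing score on a used variable yields an explicit
    unclassifiable result.
    """
    node = spec.nodes[spec.root_id]
    pathway: list[tuple[str, float, str]] = []
    guard = 0
    while node.kind == "internal":
        guard += 1
        if guard > len(spec.nodes):
            raise SpecValidationError("routing did not terminate (cycle in spec)")
        v = scores.get(node.variable)  # type: ignore[arg-type]
        if v is None:
            return ClassificationResult(
                node_id=None, predicted_block_lt_07=None,
                predicted_block_lt_09=None, pathway=tuple(pathway),
                missing=node.variable,
            )
        direction = "right" if v >= node.threshold else "left"
        pathway.append((node.variable, node.threshold, direction))  # type: ignore[arg-type]
        child = node.right if direction == "right" else node.left
        if child not in spec.nodes:
            raise SpecValidationError(
                f"node {node.id} points to missing child {child}"
            )
        node = spec.nodes[child]
    return ClassificationResult(
        node_id=node.id,
        predicted_block_lt_07=node.block_lt_07,
        predicted_block_lt_09=node.block_lt_09,
        pathway=tuple(pathway),
    )


def classify_cohort(
    records: Iterable[PatientRecord], spec: DecisionTreeSpec
) -> list[ClassificationResult]:
    return [classify(r.scores, spec) for r in records]


# ---------------------------------------------------------------------------
# Validation


@dataclass
class ValidationReport:
    valid: bool
    errors: list[str] = field(default_factory=list)


def _score_lattice(variables: Sequence[str]) -> Iterable[dict[str, int]]:
    ranges = [range(SCORE_RANGES[v][0], SCORE_RANGES[v][1] + 1)
              for v in variables]
    for combo in itertools.product(*ranges):
        yield dict(zip(variables, combo))


def validate_spec(spec: DecisionTreeSpec) -> ValidationReport:
    """Structural and routing validation of a tree spec.

    Checks: node ids unique (enforced at load), exactly one root, every
    child pointer resolves, no node has two parents, no cycles, routing is
    total over the finite score lattice restricted to the used variables,
    and every terminal node is reachable by some score vector.
    """
    errors: list[str] = []
    parents: dict[int, list[int]] = {}
    for i, nd in spec.nodes.items():
        if nd.kind == "internal":
            for child in (nd.left, nd.right):
                if child is None or child not in spec.nodes:
                    errors.append(f"node {i} points to missing child {child}")
                else:
                    parents.setdefault(child, []).append(i)
            if nd.variable not in SCORE_RANGES:
                errors.append(f"node {i} splits unknown variable {nd.variable!r}")
        elif nd.kind != "terminal":
            errors.append(f"node {i} has unknown kind {nd.kind!r}")
    for child, ps in parents.items():
        if len(ps) > 1:
            errors.append(
                f"node {child} has multiple parents {sorted(ps)}: "
                "routing regions would overlap"
            )
    roots = [i for i in spec.nodes if i not in parents]
    if spec.root_id not in spec.nodes:
        errors.append(f"root id {spec.root_id} not among the nodes")
    if sorted(roots) not in ([spec.root_id],):
        extra = [r for r in roots if r != spec.root_id]
        if extra:
            errors.append(f"unreachable root-like nodes: {extra}")
    if errors:
        return ValidationReport(valid=False, errors=errors)

    # routing totality + terminal reachability over the used-variable lattice
    used = spec.used_variables()
    reached: set[int] = set()
    fill = {v: SCORE_RANGES[v][0] for v in SCORE_RANGES if v not in used}
    for combo in _score_lattice(used):
        scores = TestScores(**{**fill, **combo})
        try:
            res = classify(scores, spec)
        except SpecValidationError as exc:
            errors.append(f"routing failed at {combo}: {exc}")
            return ValidationReport(valid=False, errors=errors)
        if res.node_id is None:
            errors.append(f"routing incomplete at {combo}")
            return ValidationReport(valid=False, errors=errors)
        reached.add(res.node_id)
    for t in spec.terminal_ids():
        if t not in reached:
            errors.append(f"terminal node {t} is unreachable")
    return ValidationReport(valid=not errors, errors=errors)


# ---------------------------------------------------------------------------
# Node bookkeeping used in derivation-style reporting


def node_tofr_fraction(
    records: Sequence[PatientRecord],
    spec: DecisionTreeSpec,
    node_id: int,
    below: Optional[float] = None,
    above: Optional[float] = None,
) -> tuple[int, int]:
    """Count patients routed to ``node_id`` whose EMG TOFR meets a bound.

    Returns ``(k, n)``: of the ``n`` patients in the node, ``k`` have
    EMG TOFR strictly below ``below`` (or strictly above ``above``).
    Exactly one bound must be given.
    """
    if (below is None) == (above is None):
        raise ValueError("give exactly one of 'below' or 'above'")
    n = k = 0
    for rec in records:
        res = classify(rec.scores, spec)
        if res.node_id != node_id:
            continue
        n += 1
        if below is not None and rec.emg_tofr < below:
            k += 1
        if above is not None and rec.emg_tofr > above:
            k += 1
    return k, n
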