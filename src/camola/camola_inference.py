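"""Carbon-fragment origin inference from paired labeling experiments.

The carbon-module labeling design runs the same model reaction twice: once with
a fully labeled precursor pool ("all", p = 1) and once with labeled and
unlabeled precursor mixed 1:1 ("half", p = 0.5). A product assembled from ``k``
independent precursor-derived fragments then shows a characteristic half-system
isotopologue pattern: each fragment is, independently, entirely labeled with
probability p, so the mass-shift distribution is the convolution over fragments
of two-point distributions. An intact C5 skeleton gives [M]:[M+5] = 1:1; a 2+3
assembly gives 25/25/25/25 over M, M+2, M+3, M+5; and so on.

This module enumerates candidate fragment multisets (integer partitions of the
labeled-carbon count), predicts their half-system distributions, scores them
against the observed corrected distribution by summed squared percentage error,
and classifies the compound's carbon origin:

* ``no_precursor_carbon`` — the fully labeled system shows only unshifted M.
* ``precursor_exclusive`` — the whole skeleton carries label and one fragment
  hypothesis explains the half pattern.
* ``mixed`` — part of the skeleton is precursor-derived, part is not.
* ``multi_pathway`` — no single assembly explains the half pattern (best
  distance above threshold, or the half support is unreachable), indicating
  parallel formation routes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .errors import ValidationError
from .records import CompoundRecord, CorrectedDistribution, RunConfig

_EPS = 1e-9


@dataclass(frozen=True)
class LabelingDesign:
    """Parameters of the labeling experiment.

    ``p`` is the fraction of the precursor pool that is labeled (1 in the fully
    labeled system, 0.5 in the equimolar mixed system). ``label_shift_per_carbon``
    is the mass shift per labeled unit (1 for ¹³C₆-glucose; for the
    deuterated-precursor design a "fragment size" counts labeled units and the
    shift per unit is still 1). ``precursor_carbon_count`` caps the size of any
    single fragment (6 for glucose, 5 for a D₅ label).
    """

    p: float = 0.5
    label_shift_per_carbon: int = 1
    precursor_carbon_count: int = 6

    def __post_init__(self):
        if not (0.0 <= self.p <= 1.0):
            raise ValidationError(f"labeled fraction p={self.p} outside [0, 1]")
        if self.label_shift_per_carbon < 1 or self.precursor_carbon_count < 1:
            raise ValidationError("label shift and precursor carbon count must be >= 1")


@dataclass(frozen=True)
class FragmentHypothesis:
    """A multiset of labeled-precursor fragment sizes assembling the skeleton.

    ``fragments`` is stored sorted descending; ``unlabeled_carbons`` counts
    skeleton carbons contributed by non-labeled sources (filled in when the
    compound context is known).
    """

    fragments: tuple[int, ...]
    unlabeled_carbons: int = 0

    def __post_init__(self):
        frags = tuple(sorted((int(f) for f in self.fragments), reverse=True))
        if any(f < 1 for f in frags):
            raise ValidationError(f"fragment sizes must be positive: {frags}")
        if self.unlabeled_carbons < 0:
            raise ValidationError("unlabeled_carbons must be >= 0")
        object.__setattr__(self, "fragments", frags)

    @property
    def labeled_total(self) -> int:
        return sum(self.fragments)

    def label(self) -> str:
        """Human-readable form like "2+3" (empty multiset → "0")."""
        return "+".join(str(f) for f in sorted(self.fragments)) or "0"


@dataclass
class HypothesisScore:
    hypothesis: FragmentHypothesis
    expected: CorrectedDistribution
    distance: float
    rank: int = 0
    state_weight: float = 100.0  # weight of the fully-labeled state this hypothesis explains

    def __post_init__(self):
        if self.distance < 0:
            raise ValidationError("distance must be >= 0")


@dataclass
class OriginCall:
    """Final origin classification for one compound."""

    compound: Optional[CompoundRecord]
    call: str
    best_hypotheses: list[HypothesisScore] = field(default_factory=list)
    notes: str = ""


def expected_distribution(h: FragmentHypothesis, design: LabelingDesign) -> CorrectedDistribution:
    """Predicted percent isotopologue distribution for a fragment hypothesis.

    Each fragment is independently labeled with probability ``design.p``,
    contributing ``size × label_shift_per_carbon`` mass units when labeled; the
    result is the convolution over fragments, in percent (sums to exactly 100).
    """
    dist = {0: 1.0}
    p = design.p
    for f in h.fragments:
        if f > design.precursor_carbon_count:
            raise ValidationError(
                f"fragment of {f} carbons exceeds precursor size {design.precursor_carbon_count}"
            )
        shift = f * design.label_shift_per_carbon
        new: dict[int, float] = {}
        for k, w in dist.items():
            new[k] = new.get(k, 0.0) + w * (1 - p)
            new[k + shift] = new.get(k + shift, 0.0) + w * p
        dist = new
    fractions = {k: 100.0 * w for k, w in dist.items() if w > 0}
    return CorrectedDistribution(fractions, system="expected")


def glucose_carbon_states(all_dist: CorrectedDistribution) -> list[tuple[int, float]]:
    """Support of the fully labeled (p = 1) distribution.

    Each entry (k, weight) reads: a fraction ``weight`` of product molecules
    carry ``k`` precursor-derived labeled carbons.
    """
    return [(k, v) for k, v in all_dist.fractions.items() if v > _EPS]


def _partitions(n: int, max_parts: int, cap: int, head: int) -> Iterable[tuple[int, ...]]:
    if n == 0:
        yield ()
        return
    if max_parts == 0:
        return
    for first in range(min(n, cap, head), 0, -1):
        for rest in _partitions(n - first, max_parts - 1, cap, first):
            yield (first,) + rest


def enumerate_hypotheses(
    labeled_count: int, max_fragments: int, precursor_carbon_count: int
) -> list[FragmentHypothesis]:
    """All partitions of ``labeled_count`` into ≤ max_fragments parts, each ≤ precursor size.

    Deterministic order: fewest fragments first, then lexicographically
    descending parts, e.g. for 4 carbons: (4), (3,1), (2,2).
    """
    if labeled_count < 0:
        raise ValidationError("labeled_count must be >= 0")
    parts = list(_partitions(labeled_count, max_fragments, precursor_carbon_count, labeled_count))
    parts.sort(key=lambda t: (len(t), [-x for x in t]))
    return [FragmentHypothesis(t) for t in parts]


def score_hypothesis(expected: CorrectedDistribution, observed: CorrectedDistribution) -> float:
    """Summed squared percentage difference over the union of channels."""
    keys = set(expected.fractions) | set(observed.fractions)
    return float(
        sum((expected.fractions.get(k, 0.0) - observed.fractions.get(k, 0.0)) ** 2 for k in keys)
    )


def _reachable_shifts(h: FragmentHypothesis, shift: int) -> set[int]:
    reach = {0}
    for f in h.fragments:
        reach |= {s + f * shift for s in reach}
    return reach


def classify_origin(
    all_dist: CorrectedDistribution,
    best: Optional[HypothesisScore],
    threshold: float,
    carbon_count: Optional[int] = None,
    inconsistent: bool = False,
) -> str:
    """Apply the origin-call rules; see module docstring for the categories."""
    support = {k for k, _ in glucose_carbon_states(all_dist)}
    if support == {0}:
        return "no_precursor_carbon"
    if inconsistent or best is None or best.distance > threshold:
        return "multi_pathway"
    if carbon_count is None and all_dist.compound is not None:
        carbon_count = all_dist.compound.n_carbon
    if carbon_count is not None and support == {carbon_count}:
        return "precursor_exclusive"
    return "mixed"


def infer_fragments(
    all_dist: CorrectedDistribution,
    half_dist: CorrectedDistribution,
    design: LabelingDesign,
    config: Optional[RunConfig] = None,
    compound: Optional[CompoundRecord] = None,
) -> OriginCall:
    """Infer the fragment assembly of one compound from its all/half distributions.

    For every labeled-carbon state of the fully labeled system, candidate
    fragment multisets are enumerated and their predicted half-system patterns
    scored against the observed half distribution; hypotheses are ranked by
    distance (ties: fewer fragments, then larger largest fragment). The origin
    call applies :func:`classify_origin` with the configured distance threshold.
    """
    config = config or RunConfig()
    compound = compound or all_dist.compound or half_dist.compound
    n_carbon = compound.n_carbon if compound is not None else None

    states = glucose_carbon_states(all_dist)
    scored: list[HypothesisScore] = []
    notes: list[str] = []
    reachable: set[int] = {0}
    for k, weight in states:
        if n_carbon is not None and k > n_carbon:
            notes.append(f"fully-labeled state M+{k} exceeds the {n_carbon}-carbon skeleton")
        for h in enumerate_hypotheses(k, config.max_fragments, design.precursor_carbon_count):
            if n_carbon is not None and h.labeled_total > n_carbon:
                continue
            unlabeled = (n_carbon - h.labeled_total) if n_carbon is not None else 0
            h = FragmentHypothesis(h.fragments, unlabeled_carbons=unlabeled)
            exp = expected_distribution(h, design)
            scored.append(
                HypothesisScore(h, exp, score_hypothesis(exp, half_dist), state_weight=weight)
            )
            reachable |= _reachable_shifts(h, design.label_shift_per_carbon)

    scored.sort(
        key=lambda s: (
            round(s.distance, 9),
            len(s.hypothesis.fragments),
            -(s.hypothesis.fragments[0] if s.hypothesis.fragments else 0),
        )
    )
    for i, s in enumerate(scored):
        s.rank = i + 1

    unreachable = sorted(half_dist.support - reachable)
    inconsistent = bool(unreachable)
    if inconsistent:
        notes.append(
            "half-labeled channels "
            + ", ".join(f"M+{k}" for k in unreachable)
            + " are unreachable from any fragment hypothesis of the fully-labeled states"
        )

    best = scored[0] if scored else None
    call = classify_origin(
        all_dist, best, config.distance_threshold, carbon_count=n_carbon, inconsistent=inconsistent
    )
    return OriginCall(compound=compound, call=call, best_hypotheses=scored[:5], notes="; ".join(notes))
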