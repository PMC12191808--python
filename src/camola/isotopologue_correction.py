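"""Isotopologue envelope correction.

Raw selected-ion envelopes from an electron-ionization GC–MS run are distorted
relative to the true isotopologue species distribution by two instrument/physics
effects:

1. **Molecular-ion hydrogen loss.** Under EI a fraction of every molecular-ion
   species sheds one hydrogen, shifting intensity one channel down. With loss
   ratio ``r`` (intensity at M−1 per intensity retained at M, measured on an
   unlabeled control) the observed channel ``k`` is
   ``O(k) = [T(k) + r·T(k+1)] / (1 + r)`` in terms of true species ``T``.
2. **Natural heavy-isotope abundance.** Each of the ``nC`` carbons carries ¹³C
   with probability 1.10% and each of the ``nS`` sulfurs ³³S (0.76%, +1 Da) or
   ³⁴S (4.20%, +2 Da), so every species leaks signal into the one and two
   channels above it.

This module inverts both effects and normalizes the result to a percentage
distribution over label counts. The natural-abundance inversion is sequential
first-order subtraction from the lowest channel upward — only single heavy-atom
terms are removed, matching how isotope-labeling studies with ≤ C10 volatiles
typically correct ("M+1 and M+2 contributions"). A matrix formulation
(:func:`natural_abundance_matrix` + :func:`correct_natural_abundance_matrix`)
is provided both as a cross-check and, with ``order="binomial"``, as a way to
quantify the error of ignoring multi-heavy-atom terms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

from .errors import DegenerateInputError, ValidationError
from .records import CompoundRecord, CorrectedDistribution, IsotopologueEnvelope, parse_formula

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrectionParams:
    """Constants of the two corrections.

    ``c13``/``s33``/``s34`` are per-atom natural-abundance fractions; ``r`` is
    the hydrogen-loss ratio (M−1)/M. ``hloss_scope`` selects whether the
    hydrogen-loss inversion is applied to every channel (``"all"``, default —
    the same physics affects the unlabeled species and the transform stays
    invertible) or only to labeled channels k ≥ 1 (``"labeled"``, the literal
    reading of correcting "the labeled molecular ions").
    """

    c13: float = 0.0110
    s33: float = 0.0076
    s34: float = 0.0420
    r: float = 0.0
    hloss_scope: str = "all"

    def __post_init__(self):
        for name in ("c13", "s33", "s34"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ValidationError(f"{name}={v} outside [0, 1)")
        if self.r < 0:
            raise ValidationError(f"hydrogen-loss ratio r={self.r} must be >= 0")
        if self.hloss_scope not in ("all", "labeled"):
            raise ValidationError("hloss_scope must be 'all' or 'labeled'")


def _composition(formula) -> tuple[int, int]:
    if isinstance(formula, CompoundRecord):
        return formula.n_carbon, formula.n_sulfur
    comp = parse_formula(formula) if isinstance(formula, str) else dict(formula)
    return comp.get("C", 0), comp.get("S", 0)


def estimate_hloss_ratio(control: IsotopologueEnvelope) -> float:
    """Hydrogen-loss ratio r = area(M−1)/area(M) from an unlabeled control."""
    if -1 not in control.areas:
        raise ValidationError(
            f"{control.compound.name}: control envelope has no M-1 channel; "
            "configure a fixed hloss ratio instead"
        )
    if 0 not in control.areas or control.areas[0] <= 0:
        raise DegenerateInputError(
            f"{control.compound.name}: control envelope has zero area at M, ratio undefined"
        )
    return control.areas[-1] / control.areas[0]


def correct_hydrogen_loss(env: IsotopologueEnvelope, r: float, scope: str = "all") -> IsotopologueEnvelope:
    """Invert molecular-ion hydrogen loss with ratio ``r``.

    Solves O(k) = [T(k) + r·T(k+1)]/(1+r) from the highest channel downward;
    channel −1 is dropped from the output. Negative intermediates (possible on
    noisy data) are clamped to zero with a logged warning.
    """
    if r < 0:
        raise ValidationError(f"hydrogen-loss ratio r={r} must be >= 0")
    if r == 0:
        out = {k: v for k, v in env.areas.items() if k >= 0}
        if not out:
            raise DegenerateInputError(f"{env.compound.name}/{env.system}: only channel M-1 present")
        return IsotopologueEnvelope(env.compound, env.system, out)

    offsets, obs = env.dense()
    true = np.zeros_like(obs)
    floor = 1 if scope == "labeled" else 0
    above = 0.0  # T(k+1) from the previous (higher) iteration
    for i in range(len(offsets) - 1, -1, -1):
        k = int(offsets[i])
        if k < floor:
            true[i] = obs[i]
            continue
        t = obs[i] * (1 + r) - r * above
        if t < 0:
            logger.warning(
                "%s/%s: hydrogen-loss inversion gave %.4g at channel %d; clamped to 0",
                env.compound.name, env.system, t, k,
            )
            t = 0.0
        true[i] = t
        above = t
    out = {int(k): float(v) for k, v in zip(offsets, true) if k >= 0}
    return IsotopologueEnvelope(env.compound, env.system, out)


def correct_natural_abundance(
    env: IsotopologueEnvelope, formula, params: CorrectionParams
) -> IsotopologueEnvelope:
    """Remove first-order natural heavy-isotope contributions.

    Ascending over channels, each already-corrected species at channel k−1
    contributed ``(nC·c13 + nS·s33)`` of itself to channel k (+1 Da isotopes)
    and each species at k−2 contributed ``nS·s34`` to k (+2 Da ³⁴S); both are
    subtracted. Negatives clamp to zero with a logged warning.
    """
    n_c, n_s = _composition(formula)
    a1 = n_c * params.c13 + n_s * params.s33
    a2 = n_s * params.s34
    if a1 == 0 and a2 == 0:
        return IsotopologueEnvelope(env.compound, env.system, dict(env.areas))

    offsets, obs = env.dense()
    corr = np.zeros_like(obs)
    for i in range(len(offsets)):
        v = obs[i]
        if i >= 1:
            v -= a1 * corr[i - 1]
        if i >= 2:
            v -= a2 * corr[i - 2]
        if v < 0:
            logger.warning(
                "%s/%s: natural-abundance subtraction gave %.4g at channel %d; clamped to 0",
                env.compound.name, env.system, v, int(offsets[i]),
            )
            v = 0.0
        corr[i] = v
    out = {int(k): float(v) for k, v in zip(offsets, corr)}
    return IsotopologueEnvelope(env.compound, env.system, out)


def natural_abundance_matrix(
    formula, channels: np.ndarray, params: CorrectionParams, order: str = "first"
) -> np.ndarray:
    """Forward-convolution matrix M with M[i, j] = signal at channel i per unit true species at channel j.

    ``order="first"`` keeps only the single-heavy-atom terms the sequential
    subtraction removes; ``order="binomial"`` uses the full binomial/per-atom
    convolution (carbons ~ Binomial(nC, c13); each sulfur contributes
    (1−s33−s34, s33, s34) at +0/+1/+2), which also depletes the diagonal.
    """
    n_c, n_s = _composition(formula)
    n = len(channels)
    m = np.zeros((n, n))
    if order == "first":
        a1 = n_c * params.c13 + n_s * params.s33
        a2 = n_s * params.s34
        for j in range(n):
            m[j, j] = 1.0
            if j + 1 < n:
                m[j + 1, j] += a1
            if j + 2 < n:
                m[j + 2, j] += a2
    elif order == "binomial":
        shifts = binom.pmf(np.arange(n_c + 1), n_c, params.c13)
        sulfur = np.array([1 - params.s33 - params.s34, params.s33, params.s34])
        for _ in range(n_s):
            shifts = np.convolve(shifts, sulfur)
        for j in range(n):
            for d, p in enumerate(shifts):
                if j + d < n:
                    m[j + d, j] += p
    else:
        raise ValidationError("order must be 'first' or 'binomial'")
    return m


def correct_natural_abundance_matrix(
    env: IsotopologueEnvelope, formula, params: CorrectionParams, order: str = "first"
) -> IsotopologueEnvelope:
    """Natural-abundance correction by solving the linear forward model.

    With ``order="first"`` this is algebraically identical to the sequential
    subtraction (the matrix is unit lower-triangular and forward substitution
    is its exact solve); it exists as an independent formulation and to host
    the ``"binomial"`` variant.
    """
    offsets, obs = env.dense()
    m = natural_abundance_matrix(formula, offsets, params, order=order)
    true = np.linalg.solve(m, obs)
    neg = true < 0
    if np.any(neg):
        logger.warning(
            "%s/%s: matrix inversion gave %d negative channel(s); clamped to 0",
            env.compound.name, env.system, int(neg.sum()),
        )
        true = np.clip(true, 0.0, None)
    return IsotopologueEnvelope(env.compound, env.system, {int(k): float(v) for k, v in zip(offsets, true)})


def normalize(env: IsotopologueEnvelope) -> CorrectedDistribution:
    """Percentage distribution 100·area(k)/Σ areas; exact (unrounded) fractions."""
    total = env.total()
    if total <= 0:
        raise DegenerateInputError(
            f"{env.compound.name}/{env.system}: all-zero envelope cannot be normalized"
        )
    fractions = {k: 100.0 * v / total for k, v in env.areas.items()}
    return CorrectedDistribution(fractions, compound=env.compound, system=env.system)


def correct_envelope(
    env: IsotopologueEnvelope,
    params: CorrectionParams,
    formula=None,
    method: str = "sequential",
    return_audit: bool = False,
):
    """Full correction: hydrogen loss → natural abundance → normalize.

    ``formula`` defaults to the envelope's compound formula. With
    ``return_audit=True`` the intermediate envelopes are returned alongside the
    distribution for report auditing.
    """
    formula = formula if formula is not None else env.compound
    step1 = correct_hydrogen_loss(env, params.r, scope=params.hloss_scope)
    if method == "sequential":
        step2 = correct_natural_abundance(step1, formula, params)
    else:
        step2 = correct_natural_abundance_matrix(step1, formula, params, order=method)
    dist = normalize(step2)
    if return_audit:
        return dist, {"raw": env, "hloss_corrected": step1, "abundance_corrected": step2}
    return dist
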