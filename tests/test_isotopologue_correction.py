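"""Envelope correction: hydrogen loss, natural abundance, normalization.

The independent oracle throughout is the *forward* model: build a distorted
envelope from known true species (convolution / loss split written out by hand
in this file, separate from the library's generator), then check that the
correction recovers the truth. The matrix oracle for the natural-abundance
step is also built here, brute force, and compared against the sequential
subtraction.
"""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from camola import (
    CompoundRecord,
    CorrectionParams,
    IsotopologueEnvelope,
    correct_envelope,
    correct_hydrogen_loss,
    correct_natural_abundance,
    estimate_hloss_ratio,
    normalize,
)
from camola.errors import DegenerateInputError, ValidationError
from camola.isotopologue_correction import correct_natural_abundance_matrix
from camola.records import CorrectedDistribution


def make_env(areas, formula="C5H6O2", system="all", name="test"):
    return IsotopologueEnvelope(CompoundRecord(name, formula), system, areas)


# ---------------------------------------------------------------- oracles


def forward_hloss(true: dict, r: float) -> dict:
    """Hand-written forward hydrogen-loss split: each species keeps 1/(1+r), sheds r/(1+r) to k-1."""
    obs: dict[int, float] = {}
    for k, v in true.items():
        obs[k] = obs.get(k, 0.0) + v / (1 + r)
        obs[k - 1] = obs.get(k - 1, 0.0) + v * r / (1 + r)
    return obs


def forward_abundance(true: dict, n_c: int, n_s: int, p: CorrectionParams) -> dict:
    """Hand-written first-order natural-abundance convolution."""
    a1 = n_c * p.c13 + n_s * p.s33
    a2 = n_s * p.s34
    obs = dict(true)
    for k, v in true.items():
        obs[k + 1] = obs.get(k + 1, 0.0) + a1 * v
        obs[k + 2] = obs.get(k + 2, 0.0) + a2 * v
    return obs


def matrix_correct(obs_env: IsotopologueEnvelope, n_c: int, n_s: int, p: CorrectionParams) -> dict:
    """Brute-force matrix oracle: assemble the forward-convolution matrix column by
    column and solve the linear system."""
    offsets, obs = obs_env.dense()
    n = len(offsets)
    m = np.zeros((n, n))
    a1 = n_c * p.c13 + n_s * p.s33
    a2 = n_s * p.s34
    for j in range(n):
        unit = np.zeros(n)
        unit[j] = 1.0
        if j + 1 < n:
            unit[j + 1] = a1
        if j + 2 < n:
            unit[j + 2] = a2
        m[:, j] = unit
    true = np.linalg.solve(m, obs)
    return {int(k): float(v) for k, v in zip(offsets, true)}


# ------------------------------------------------------- hydrogen loss


@pytest.mark.parametrize(
    "areas, expected",
    [({-1: 10, 0: 100}, 0.10), ({-1: 0, 0: 100}, 0.0), ({-1: 25, 0: 50}, 0.5)],
)
def test_estimate_hloss_ratio(areas, expected):
    assert estimate_hloss_ratio(make_env(areas, system="control")) == pytest.approx(expected)


def test_estimate_hloss_ratio_errors():
    with pytest.raises(ValidationError, match="M-1"):
        estimate_hloss_ratio(make_env({0: 100}, system="control"))
    with pytest.raises(DegenerateInputError):
        estimate_hloss_ratio(make_env({-1: 5, 0: 0, 1: 3}, system="control"))


def test_hloss_zero_ratio_is_identity_minus_minus1():
    env = make_env({-1: 7, 0: 100, 2: 50})
    out = correct_hydrogen_loss(env, 0.0)
    assert out.areas == {0: 100, 2: 50}


@pytest.mark.parametrize(
    "true, r",
    [({0: 100.0}, 0.1), ({5: 60.0, 4: 40.0}, 0.5), ({0: 10.0, 2: 30.0, 3: 60.0}, 0.25)],
)
def test_hloss_inverts_forward_projection(true, r):
    obs = forward_hloss(true, r)
    recovered = correct_hydrogen_loss(make_env(obs), r)
    for k, v in true.items():
        assert recovered.areas[k] == pytest.approx(v, abs=1e-9)
    assert -1 not in recovered.areas
    assert sum(recovered.areas.values()) == pytest.approx(sum(true.values()))


def test_hloss_forward_projection_example():
    # true {0: 100} with r = 0.1 observes 9.0909.. at M-1 and 90.9090.. at M
    obs = forward_hloss({0: 100.0}, 0.1)
    assert obs[-1] == pytest.approx(100 / 11)
    assert obs[0] == pytest.approx(1000 / 11)


# --------------------------------------------------- natural abundance


def test_abundance_identity_without_heavy_atoms():
    env = make_env({0: 1000, 1: 55}, formula="C5H6O2")
    out = correct_natural_abundance(env, "C5H6O2", CorrectionParams(c13=0, s33=0, s34=0))
    assert out.areas == env.areas


def test_abundance_c5_first_order():
    # C5 compound, true {0: 1000}: forward puts 5 x 1.10% = 55 into M+1
    p = CorrectionParams()
    obs = forward_abundance({0: 1000.0}, 5, 0, p)
    assert obs[1] == pytest.approx(55.0)
    out = correct_natural_abundance(make_env(obs, formula="C5H10O"), "C5H10O", p)
    assert out.areas[0] == pytest.approx(1000.0)
    assert out.areas[1] == pytest.approx(0.0, abs=1e-9)


def test_abundance_sulfur_contributions():
    # C4S1: M+1 gets 4*0.0110 + 0.0076 = 0.0516, M+2 gets 0.0420
    p = CorrectionParams()
    obs = forward_abundance({0: 1000.0}, 4, 1, p)
    assert obs[1] == pytest.approx(51.6)
    assert obs[2] == pytest.approx(42.0)
    out = correct_natural_abundance(make_env(obs, formula="C4H8S"), "C4H8S", p)
    assert out.areas[0] == pytest.approx(1000.0)
    assert out.areas[1] == pytest.approx(0.0, abs=1e-9)
    assert out.areas[2] == pytest.approx(0.0, abs=1e-9)


@st.composite
def dist_and_formula(draw):
    n_channels = draw(st.integers(2, 6))
    weights = draw(
        st.lists(st.floats(0.0, 100.0), min_size=n_channels, max_size=n_channels).filter(
            lambda w: sum(w) > 1
        )
    )
    total = sum(weights)
    dist = {k: 100.0 * w / total for k, w in enumerate(weights)}
    n_c = draw(st.integers(1, 10))
    n_s = draw(st.integers(0, 1))
    formula = f"C{n_c}H{2 * n_c}" + ("S" if n_s else "")
    return dist, formula, n_c, n_s


@given(dist_and_formula(), st.floats(0.0, 0.5))
def test_sequential_agrees_with_matrix_oracle_and_roundtrips(case, r):
    dist, formula, n_c, n_s = case
    p = CorrectionParams(r=r)
    obs = forward_abundance(dist, n_c, n_s, p)

    seq = correct_natural_abundance(make_env(obs, formula=formula), formula, p)
    oracle = matrix_correct(make_env(obs, formula=formula), n_c, n_s, p)
    for k in oracle:
        # agreement expressed in percentage points of the total signal
        diff = 100 * abs(seq.areas.get(k, 0.0) - oracle[k]) / sum(dist.values())
        assert diff < 0.1

    # full round trip via hydrogen loss as well
    obs2 = forward_hloss(obs, r) if r > 0 else obs
    recovered = correct_envelope(
        make_env(obs2, formula=formula), p, formula=formula
    )
    for k, v in dist.items():
        assert recovered.fractions.get(k, 0.0) == pytest.approx(v, abs=0.5)


def test_matrix_method_matches_sequential():
    p = CorrectionParams()
    obs = forward_abundance({0: 500.0, 3: 500.0}, 6, 1, p)
    env = make_env(obs, formula="C6H12S")
    seq = correct_natural_abundance(env, "C6H12S", p)
    mat = correct_natural_abundance_matrix(env, "C6H12S", p, order="first")
    for k in seq.areas:
        assert seq.areas[k] == pytest.approx(mat.areas[k], abs=1e-9)


def test_clamping_negative_intermediates(caplog):
    import logging

    env = make_env({0: 100, 1: 0.1}, formula="C9H18O2")  # M+1 far below natural abundance
    with caplog.at_level(logging.WARNING):
        out = correct_natural_abundance(env, "C9H18O2", CorrectionParams())
    assert out.areas[1] == 0.0
    assert any("clamped" in r.message for r in caplog.records)


# ------------------------------------------------------------ normalize


@pytest.mark.parametrize(
    "areas, expected",
    [
        ({4: 2000, 5: 3000}, {4: 40.0, 5: 60.0}),
        ({0: 7}, {0: 100.0}),
        ({0: 1, 3: 1, 5: 1}, {0: 100 / 3, 3: 100 / 3, 5: 100 / 3}),
    ],
)
def test_normalize(areas, expected):
    dist = normalize(make_env(areas))
    assert dist.fractions == pytest.approx(expected)
    assert sum(dist.fractions.values()) == pytest.approx(100.0)


def test_normalize_all_zero_errors():
    with pytest.raises(DegenerateInputError, match="test"):
        normalize(make_env({0: 0.0, 1: 0.0}))


# ------------------------------------------------------- full pipeline


def test_correct_envelope_zero_params_equals_normalize():
    env = make_env({0: 10, 2: 30, 5: 60})
    p = CorrectionParams(c13=0, s33=0, s34=0, r=0)
    assert correct_envelope(env, p).fractions == pytest.approx(normalize(env).fractions)


def test_correct_envelope_full_forward_roundtrip():
    true = {0: 25.0, 2: 25.0, 3: 25.0, 5: 25.0}
    p = CorrectionParams(r=0.15)
    obs = forward_hloss(forward_abundance(true, 5, 0, p), p.r)
    dist = correct_envelope(make_env(obs, formula="C5H6N2"), p, formula="C5H6N2")
    for k, v in true.items():
        assert dist.fractions[k] == pytest.approx(v, abs=0.5)


def test_unlabeled_control_stays_pure():
    # a compound whose skeleton has no precursor carbon keeps 100% at M
    p = CorrectionParams(r=0.1)
    obs = forward_hloss(forward_abundance({0: 1000.0}, 7, 0, p), p.r)
    dist = correct_envelope(make_env(obs, formula="C7H6O", name="benzaldehyde"), p)
    assert dist.fractions[0] == pytest.approx(100.0, abs=1e-6)


def test_audit_returns_intermediates():
    env = make_env({-1: 5, 0: 100, 1: 6})
    dist, audit = correct_envelope(env, CorrectionParams(r=0.05), return_audit=True)
    assert set(audit) == {"raw", "hloss_corrected", "abundance_corrected"}
    assert -1 not in audit["hloss_corrected"].areas


@given(st.permutations([0, 1, 2, 3, 4]))
def test_channel_order_invariance(order):
    base = {0: 10.0, 1: 20.0, 2: 5.0, 3: 40.0, 4: 25.0}
    shuffled = {k: base[k] for k in order}
    p = CorrectionParams(r=0.1)
    a = correct_envelope(make_env(base), p)
    b = correct_envelope(make_env(shuffled), p)
    assert a.fractions == pytest.approx(b.fractions)


@given(st.floats(0.001, 1e6))
def test_scale_invariance(scale):
    base = {0: 10.0, 2: 30.0, 5: 60.0}
    p = CorrectionParams(r=0.2)
    a = correct_envelope(make_env(base), p)
    b = correct_envelope(make_env({k: v * scale for k, v in base.items()}), p)
    for k in a.fractions:
        assert a.fractions[k] == pytest.approx(b.fractions[k], abs=1e-6)
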