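"""Loss-function unit and property tests.

The oracle functions below re-type the loss formulas in plain ``math``
scalar arithmetic, sharing no code with the package, so agreement is a
genuine cross-check of the vectorised implementations.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glaucnet.losses import (
    EPS,
    LossConfig,
    aggregate_prob,
    batch_loss,
    correntropy_loss,
    cross_entropy,
    fc_loss,
    fc_loss_grad,
    focal_loss,
)

# ---------------------------------------------------------------- oracles


def oracle_cross_entropy(p, a):
    p = min(max(p, EPS), 1 - EPS)
    return -a * math.log(p) - (1 - a) * math.log(1 - p)


def oracle_m(p, a):
    return p if a == 1 else 1 - p


def oracle_focal(p, a, gamma, theta, balanced):
    m = min(max(oracle_m(p, a), EPS), 1 - EPS)
    w = (theta if a == 1 else 1 - theta) if balanced else theta
    return -w * (1 - m) ** gamma * math.log(m)


def oracle_correntropy(p, a, beta, two_beta_sq=False):
    d = 2 * beta * beta if two_beta_sq else beta * beta
    e = a - p
    return 1 - math.exp(-e * e / d)


def oracle_fc(p, a, epoch, cfg: LossConfig):
    if epoch < cfg.switch_epoch:
        return oracle_focal(p, a, cfg.gamma, cfg.theta, cfg.class_balanced)
    return oracle_correntropy(p, a, cfg.beta, cfg.kernel_denominator == "two_beta_sq")


def random_config(rng):
    return LossConfig(
        gamma=float(rng.uniform(0, 5)),
        theta=float(rng.uniform(0.05, 1.0)),
        beta=float(rng.uniform(0.2, 3.0)),
        switch_epoch=int(rng.integers(0, 21)),
        total_epochs=20 + int(rng.integers(1, 10)),
        class_balanced=bool(rng.integers(0, 2)),
        kernel_denominator=["beta_sq", "two_beta_sq"][rng.integers(0, 2)],
    )


# ------------------------------------------------------- hand-derived values


@pytest.mark.parametrize(
    "fn, args, expected",
    [
        (cross_entropy, (1 - 1e-9, 1), 0.0),
        (cross_entropy, (1e-9, 0), 0.0),
        (cross_entropy, (0.5, 1), math.log(2)),
        (aggregate_prob, (0.9, 1), 0.9),
        (aggregate_prob, (0.9, 0), 0.1),
    ],
)
def test_elementary_values(fn, args, expected):
    assert fn(*args) == pytest.approx(expected, abs=1e-6)


def test_focal_hand_value():
    """gamma=2, theta=1, unbalanced: 0.01 * (-ln 0.9) for (p=0.9, a=1)."""
    cfg = LossConfig(gamma=2, theta=1, class_balanced=False)
    assert focal_loss(0.9, 1, cfg) == pytest.approx(0.01 * -math.log(0.9), rel=1e-12)


def test_correntropy_hand_value():
    """|e| = beta with denominator beta^2 gives 1 - 1/e."""
    cfg = LossConfig(beta=0.5, kernel_denominator="beta_sq")
    assert correntropy_loss(0.5, 1, cfg) == pytest.approx(1 - math.exp(-1), rel=1e-12)


def test_correntropy_two_beta_sq_convention():
    cfg = LossConfig(beta=0.5, kernel_denominator="two_beta_sq")
    assert correntropy_loss(0.5, 1, cfg) == pytest.approx(1 - math.exp(-0.5), rel=1e-12)


# ------------------------------------------------------------- oracle sweep


def test_losses_match_scalar_oracle():
    """All four losses agree with the plain-arithmetic oracle on 1,000
    random (input, config) pairs to 1e-9."""
    rng = np.random.default_rng(42)
    for _ in range(1000):
        p = float(rng.uniform(1e-6, 1 - 1e-6))
        a = int(rng.integers(0, 2))
        cfg = random_config(rng)
        epoch = int(rng.integers(0, cfg.total_epochs))
        assert cross_entropy(p, a) == pytest.approx(oracle_cross_entropy(p, a), abs=1e-9)
        assert focal_loss(p, a, cfg) == pytest.approx(
            oracle_focal(p, a, cfg.gamma, cfg.theta, cfg.class_balanced), abs=1e-9
        )
        assert correntropy_loss(p, a, cfg) == pytest.approx(
            oracle_correntropy(p, a, cfg.beta, cfg.kernel_denominator == "two_beta_sq"),
            abs=1e-9,
        )
        assert fc_loss(p, a, epoch, cfg) == pytest.approx(
            oracle_fc(p, a, epoch, cfg), abs=1e-9
        )


def test_batch_loss_matches_loop_oracle():
    rng = np.random.default_rng(7)
    cfg = random_config(rng)
    epoch = int(rng.integers(0, cfg.total_epochs))
    p = rng.uniform(0.01, 0.99, size=37)
    a = rng.integers(0, 2, size=37)
    expected = sum(oracle_fc(pi, ai, epoch, cfg) for pi, ai in zip(p, a)) / 37
    assert batch_loss(p, a, epoch, cfg) == pytest.approx(expected, abs=1e-12)
    # batch of one equals the scalar loss
    assert batch_loss([p[0]], [a[0]], epoch, cfg) == pytest.approx(
        float(fc_loss(p[0], a[0], epoch, cfg)), abs=1e-15
    )


# ---------------------------------------------------------------- properties


@given(p=st.floats(1e-6, 1 - 1e-6), a=st.integers(0, 1))
@settings(max_examples=200, derandomize=True)
def test_eq3_identity(p, a):
    """cross_entropy == -log(aggregate_prob) to 1e-12."""
    assert cross_entropy(p, a) == pytest.approx(
        -math.log(aggregate_prob(p, a)), abs=1e-12
    )


@given(p=st.floats(1e-6, 1 - 1e-6), a=st.integers(0, 1))
@settings(max_examples=200, derandomize=True)
def test_focal_reduces_to_cross_entropy(p, a):
    cfg = LossConfig(gamma=0.0, theta=1.0, class_balanced=False)
    assert focal_loss(p, a, cfg) == pytest.approx(cross_entropy(p, a), abs=1e-12)


def test_focal_monotone_in_gamma():
    """For m < 1 the focal loss is non-increasing in gamma."""
    gammas = np.linspace(0, 6, 25)
    for p, a in [(0.3, 1), (0.8, 1), (0.4, 0), (0.95, 0)]:
        vals = [
            float(focal_loss(p, a, LossConfig(gamma=g, theta=0.5, class_balanced=False)))
            for g in gammas
        ]
        assert all(v1 >= v2 - 1e-15 for v1, v2 in zip(vals, vals[1:]))


def test_correntropy_bounds_and_monotonicity():
    cfg = LossConfig(beta=0.7)
    errors = np.linspace(0, 0.999, 200)
    vals = np.asarray([float(correntropy_loss(1.0 - e, 1, cfg)) for e in errors])
    assert np.all(vals >= 0) and np.all(vals < 1)
    assert np.all(np.diff(vals) > 0)  # strictly increasing in |e|
    assert float(correntropy_loss(0.25, 0, cfg)) == float(correntropy_loss(0.75, 1, cfg))


def _loss_at_error(e, cfg):
    """Correntropy loss at signed error e = a - p, via a valid (p, a)."""
    return float(correntropy_loss(1.0 - e, 1, cfg) if e >= 0
                 else correntropy_loss(-e, 0, cfg))


def test_correntropy_quadratic_small_error_limit():
    """For |e| <= 0.01*beta, |L - e^2/D| <= (e^2/D)^2 / 2."""
    for beta in (0.3, 1.0, 2.5):
        for denom in ("beta_sq", "two_beta_sq"):
            cfg = LossConfig(beta=beta, kernel_denominator=denom)
            d = cfg.kernel_d
            for e in np.linspace(-0.01 * beta, 0.01 * beta, 41):
                q = e * e / d
                assert abs(_loss_at_error(e, cfg) - q) <= q * q / 2 + 1e-18


def test_fc_schedule_bit_exact():
    """fc_loss bit-equals the active branch on both sides of switch_epoch."""
    rng = np.random.default_rng(3)
    for switch, total in [(0, 5), (3, 5), (5, 5), (1, 2), (7, 20)]:
        cfg = LossConfig(switch_epoch=switch, total_epochs=total)
        p = rng.uniform(0.05, 0.95, size=8)
        a = rng.integers(0, 2, size=8)
        for epoch in range(total):
            got = fc_loss(p, a, epoch, cfg)
            ref = focal_loss(p, a, cfg) if epoch < switch else correntropy_loss(p, a, cfg)
            assert np.array_equal(got, ref)


def test_fc_grad_matches_finite_differences():
    rng = np.random.default_rng(11)
    for _ in range(50):
        cfg = random_config(rng)
        epoch = int(rng.integers(0, cfg.total_epochs))
        p = float(rng.uniform(0.05, 0.95))
        a = int(rng.integers(0, 2))
        h = 1e-6
        fd = (
            float(fc_loss(p + h, a, epoch, cfg)) - float(fc_loss(p - h, a, epoch, cfg))
        ) / (2 * h)
        assert float(fc_loss_grad(p, a, epoch, cfg)) == pytest.approx(fd, rel=1e-4, abs=1e-7)


# ------------------------------------------------------------------- errors


def test_domain_errors():
    cfg = LossConfig()
    with pytest.raises(ValueError):
        cross_entropy(1.5, 1)
    with pytest.raises(ValueError):
        cross_entropy(-0.1, 0)
    with pytest.raises(ValueError):
        fc_loss(0.5, 1, cfg.total_epochs, cfg)  # epoch beyond schedule
    with pytest.raises(ValueError):
        batch_loss([], [], 0, cfg)
    # exactly 0/1 are clipped, never infinite
    assert np.isfinite(cross_entropy(0.0, 1))
    assert np.isfinite(cross_entropy(1.0, 0))


def test_config_validation():
    with pytest.raises(ValueError):
        LossConfig(gamma=-1)
    with pytest.raises(ValueError):
        LossConfig(theta=0)
    with pytest.raises(ValueError):
        LossConfig(beta=0)
    with pytest.raises(ValueError):
        LossConfig(switch_epoch=31, total_epochs=30)
    with pytest.raises(ValueError):
        LossConfig(kernel_denominator="bad")
    cfg = LossConfig()
    assert LossConfig.from_dict(cfg.to_dict()) == cfg
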