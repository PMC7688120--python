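"""Wright-Fisher neutral-drift null for the all-or-none pattern.

The per-line model is the discrete Wright-Fisher chain on focal-allele gamete
counts 0..2N: each generation the count is drawn Binomial(2N, p') with
p' = p(1+s)/(1+ps) (genic selection; s = 0 is pure drift).  States 0 and 2N
are absorbing.  With replicate lines evolving independently from a common
starting frequency p0, the probability that a locus shows the all-or-none
pattern is a closed-form function of the single-line fixation probabilities,
evaluated here exactly (dense transition matrix, feasible for 2N <= 200) and
by Monte Carlo for larger populations or as a cross-check.

With Ne = 35 and 88 generations (the defaults, from the high-runner breeding
design) a neutral locus at p0 = 0.5 has ~72% probability of being absorbed,
split evenly between the two alleles; the all-or-none pattern additionally
requires the four lines of one type to fix the *same* allele while no line of
the other type does, which is why its neutral probability is small and why an
excess of such loci argues against pure drift.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .model import CapabilityError, DriftNullResult, ParameterError

MAX_DENSE_TWO_N = 200

_MODES = ("not_fixed_for_focal", "strict_polymorphic")


def _check_args(p0: float, two_n: int, generations: int) -> None:
    if not 0.0 <= p0 <= 1.0:
        raise ParameterError(f"p0 must be in [0, 1], got {p0}")
    if two_n < 2:
        raise ParameterError(f"two_n must be >= 2, got {two_n}")
    if generations < 0:
        raise ParameterError(f"generations must be >= 0, got {generations}")


def selection_prob(p: np.ndarray | float, s: float) -> np.ndarray | float:
    """Post-selection transmission probability p(1+s)/(1+ps) of the focal allele."""
    if s <= -1.0:
        raise ParameterError(f"selection coefficient must be > -1, got {s}")
    return p * (1.0 + s) / (1.0 + p * s)


def transition_matrix(two_n: int, s: float = 0.0) -> np.ndarray:
    """Dense (2N+1) x (2N+1) Wright-Fisher transition matrix; rows sum to 1."""
    if two_n > MAX_DENSE_TWO_N:
        raise CapabilityError(
            f"two_n={two_n} exceeds the dense-matrix limit ({MAX_DENSE_TWO_N}); "
            "use the Monte-Carlo routines instead"
        )
    counts = np.arange(two_n + 1)
    p = selection_prob(counts / two_n, s)
    return stats.binom.pmf(counts[None, :], two_n, np.asarray(p)[:, None])


def initial_state(p0: float, two_n: int, initial: str = "round") -> np.ndarray:
    """Starting distribution over counts: nearest integer, or a two-point
    mixture over the adjacent counts weighted by the fractional part."""
    v = np.zeros(two_n + 1)
    x = p0 * two_n
    if initial == "round":
        v[int(round(x))] = 1.0
    elif initial == "mixture":
        lo = int(np.floor(x))
        frac = x - lo
        v[lo] += 1.0 - frac
        if frac > 0:
            v[lo + 1] += frac
    else:
        raise ParameterError(f"unknown initial scheme {initial!r}")
    return v


def exact_state_distribution(
    p0: float,
    two_n: int,
    generations: int,
    s: float = 0.0,
    initial: str = "round",
) -> np.ndarray:
    """Exact distribution over allele counts 0..2N after ``generations`` steps."""
    _check_args(p0, two_n, generations)
    v = initial_state(p0, two_n, initial)
    if generations == 0:
        return v
    T = transition_matrix(two_n, s)
    for _ in range(generations):
        v = v @ T
    return v


def _state_probs(dist: np.ndarray, two_n: int, delta: float) -> tuple[float, float, float]:
    """(P fixed focal, P fixed other, P segregating) under tolerance delta."""
    freqs = np.arange(two_n + 1) / two_n
    a = float(dist[freqs >= 1.0 - delta].sum())
    b = float(dist[freqs <= delta].sum())
    return a, b, max(0.0, 1.0 - a - b)


def _pattern_prob(
    a: float, b: float, seg: float, n_selected: int, n_control: int, mode: str
) -> float:
    """P(all-or-none pattern) from single-line state probabilities.

    Under ``not_fixed_for_focal`` the four direction terms overlap in the
    configuration "one type all fixed focal, the other all fixed other",
    which satisfies two directions at once; inclusion-exclusion removes the
    double count.  Under ``strict_polymorphic`` the terms are disjoint.
    """
    ns, nc = n_selected, n_control
    if mode == "not_fixed_for_focal":
        p = (
            a**ns * (1 - a) ** nc
            + b**ns * (1 - b) ** nc
            + a**nc * (1 - a) ** ns
            + b**nc * (1 - b) ** ns
        )
        p -= a**ns * b**nc + b**ns * a**nc
        return p
    return (a**ns + b**ns) * seg**nc + (a**nc + b**nc) * seg**ns


def p_all_or_none_neutral(
    p0: float,
    ne: int = 35,
    generations: int = 88,
    n_selected: int = 4,
    n_control: int = 4,
    mode: str = "not_fixed_for_focal",
    delta: float = 0.0,
    initial: str = "round",
) -> DriftNullResult:
    """Exact neutral probability that one locus shows the all-or-none pattern.

    All lines drift independently from the same p0 with s = 0; fixation uses
    tolerance ``delta`` and the non-fixed side uses the chosen ``mode``.
    """
    if mode not in _MODES:
        raise ParameterError(f"unknown mode {mode!r}; expected one of {_MODES}")
    if not 0.0 <= delta < 0.5:
        raise ParameterError(f"delta must be in [0, 0.5), got {delta}")
    if ne < 1:
        raise ParameterError(f"ne must be >= 1, got {ne}")
    two_n = 2 * ne
    dist = exact_state_distribution(p0, two_n, generations, s=0.0, initial=initial)
    a, b, seg = _state_probs(dist, two_n, delta)
    p_aon = _pattern_prob(a, b, seg, n_selected, n_control, mode)
    return DriftNullResult(
        p0=p0,
        two_n=two_n,
        generations=generations,
        p_fix_focal=a,
        p_fix_other=b,
        p_segregating=seg,
        p_all_or_none=p_aon,
        mode=mode,
        delta=delta,
    )


# ---------------------------------------------------------------------------
# Monte Carlo

def mc_final_counts(
    p0: float,
    two_n: int,
    generations: int,
    s: float = 0.0,
    reps: int = 10_000,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """``reps`` independent Wright-Fisher endpoints, vectorized across replicates.

    Mirrors the exact chain: each replicate starts at count round(p0 * 2N).
    Absorbing states are preserved automatically (Binomial with p in {0, 1}).
    """
    _check_args(p0, two_n, generations)
    if rng is None:
        rng = np.random.default_rng()
    counts = np.full(reps, int(round(p0 * two_n)), dtype=np.int64)
    for _ in range(generations):
        p = selection_prob(counts / two_n, s)
        counts = rng.binomial(two_n, p)
    return counts


def mc_fixation_probs(
    p0: float,
    two_n: int,
    generations: int,
    s: float = 0.0,
    reps: int = 10_000,
    delta: float = 0.0,
    rng: np.random.Generator | None = None,
) -> dict:
    """Monte-Carlo (P fix focal, P fix other, P segregating) with binomial SEs."""
    counts = mc_final_counts(p0, two_n, generations, s=s, reps=reps, rng=rng)
    freqs = counts / two_n
    a = float(np.mean(freqs >= 1.0 - delta))
    b = float(np.mean(freqs <= delta))
    se = lambda p: float(np.sqrt(p * (1.0 - p) / reps))  # noqa: E731
    return {
        "p_fix_focal": a,
        "p_fix_other": b,
        "p_segregating": 1.0 - a - b,
        "se_fix_focal": se(a),
        "se_fix_other": se(b),
        "reps": reps,
    }


def mc_p_all_or_none(
    p0: float,
    ne: int = 35,
    generations: int = 88,
    n_selected: int = 4,
    n_control: int = 4,
    mode: str = "not_fixed_for_focal",
    delta: float = 0.0,
    reps: int = 10_000,
    rng: np.random.Generator | None = None,
) -> dict:
    """Monte-Carlo estimate of the all-or-none probability: simulate ``reps``
    loci x (n_selected + n_control) independent lines, classify each locus."""
    if mode not in _MODES:
        raise ParameterError(f"unknown mode {mode!r}")
    if rng is None:
        rng = np.random.default_rng()
    two_n = 2 * ne
    n_lines = n_selected + n_control
    counts = np.full((reps, n_lines), int(round(p0 * two_n)), dtype=np.int64)
    for _ in range(generations):
        counts = rng.binomial(two_n, counts / two_n)
    freqs = counts / two_n
    sel, con = freqs[:, :n_selected], freqs[:, n_selected:]

    def _aon(fix_grp: np.ndarray, other_grp: np.ndarray) -> np.ndarray:
        hit = np.zeros(len(fix_grp), dtype=bool)
        for hi, lo in ((1.0 - delta, None), (None, delta)):  # focal-fixed, other-fixed
            if hi is not None:
                fixed = (fix_grp >= hi).all(axis=1)
                f_other = other_grp
            else:
                fixed = (fix_grp <= lo).all(axis=1)
                f_other = 1.0 - other_grp
            if mode == "not_fixed_for_focal":
                fails = (f_other < 1.0 - delta).all(axis=1)
            else:
                fails = ((f_other > delta) & (f_other < 1.0 - delta)).all(axis=1)
            hit |= fixed & fails
        return hit

    is_aon = _aon(sel, con) | _aon(con, sel)
    p_hat = float(is_aon.mean())
    return {
        "p_all_or_none": p_hat,
        "se": float(np.sqrt(p_hat * (1.0 - p_hat) / reps)),
        "reps": reps,
    }


def expected_all_or_none_count(
    panel_p0s: list[float] | np.ndarray,
    ne: int = 35,
    generations: int = 88,
    n_selected: int = 4,
    n_control: int = 4,
    mode: str = "not_fixed_for_focal",
    delta: float = 0.0,
    mc_reps: int = 2_000,
    rng: np.random.Generator | None = None,
) -> DriftNullResult | None:
    """Expected genome-wide all-or-none count of a neutral panel, with 95% CI.

    The expectation is the sum of exact per-locus probabilities (loci are
    independent); the CI is the 2.5-97.5 percentile band of the count obtained
    by resampling each locus as a Bernoulli draw with its exact probability,
    which is distributionally identical to simulating the whole panel under
    neutrality.  Returns ``None`` for an empty panel.
    """
    p0s = np.asarray(panel_p0s, dtype=float)
    if p0s.size == 0:
        return None
    if rng is None:
        rng = np.random.default_rng()
    cache: dict[float, float] = {}
    per_locus = np.empty(p0s.size)
    for i, p0 in enumerate(p0s):
        key = round(float(p0), 12)
        if key not in cache:
            cache[key] = p_all_or_none_neutral(
                float(p0), ne=ne, generations=generations, n_selected=n_selected,
                n_control=n_control, mode=mode, delta=delta,
            ).p_all_or_none
        per_locus[i] = cache[key]
    expected = float(per_locus.sum())
    draws = rng.random((mc_reps, p0s.size)) < per_locus[None, :]
    sim_counts = draws.sum(axis=1)
    lo, hi = np.percentile(sim_counts, [2.5, 97.5])
    return DriftNullResult(
        p0=float(np.mean(p0s)),
        two_n=2 * ne,
        generations=generations,
        p_fix_focal=float("nan"),
        p_fix_other=float("nan"),
        p_segregating=float("nan"),
        p_all_or_none=float(np.mean(per_locus)),
        mode=mode,
        delta=delta,
        expected_count=expected,
        mc_ci=(float(lo), float(hi)),
    )
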