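"""Estimating the number of protomolecules per labeled degree sequence.

Beyond the exact-enumeration range, counts rest on the small-world property
of the *universe graph* U(d): one vertex per protomolecule of degree sequence
d, edges between pairs at minimal edit distance.  For small-world networks
the average path length l_G grows like the log of the vertex count, so

    ln |U(d)|  ~=  a7 * l_G + b7                                  (base tier)

with default constants a7 = 1.220, b7 = -0.7295 obtained at database scale;
they are refittable from local exact data.  Natural logs are used throughout
(the calibration constants absorb the base convention).

Nonpure sequences are reduced to their pure counterpart: assuming large
random molecular graphs are asymmetric, introducing extra elements of a
valence multiplies the count by the combinatorial factor

    N_P(d) = prod_v prod_i C(sum_{j>=i} c_j, c_i)

and correspondingly stretches the path length,

    l_G(d) = (1 + ln N_P(d) / sum_i d_i) * l_G(d_U).              (pure tier)

For very large pure sequences the asymptotic multigraph count G (prefactor
M!/((M/2)! 2^(M/2) prod k_i!) times exponential corrections in the falling-
factorial sums M_r) feeds a second calibrated line

    l_G  ~=  a10 * ln G + b10      (a10 = 0.7561, b10 = -14.40)

after dividing G by t! where t is the monovalent-atom excess over the least
hydrogenated realizable formula with the same heavy-atom profile (the raw
relation keeps growing as monovalent atoms saturate the graph; empirically it
overestimates by t!).                                        (asymptotic tier)
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .exact import DEFAULT_ATOM_CAP, count_exact
from .formulas import is_realizable
from .space import LabeledDegreeSequence


@dataclass(frozen=True)
class CalibrationConstants:
    """Slopes/intercepts of the two calibrated lines (natural-log convention)."""

    a7: float = 1.220
    b7: float = -0.7295
    a10: float = 0.7561
    b10: float = -14.40

    def __post_init__(self) -> None:
        if self.a7 <= 0 or self.a10 <= 0:
            raise ValueError("calibration slopes must be positive")


DEFAULT_CALIBRATION = CalibrationConstants()


@dataclass(frozen=True)
class CountRecord:
    """Count (exact or estimated) for one degree sequence, with provenance."""

    key: str
    tier: str  # exact | base | pure | asymptotic
    count: float
    l_G: float | None = None
    n_pairs: int = 0
    seed: int | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if self.tier not in ("exact", "base", "pure", "asymptotic"):
            raise ValueError(f"unknown tier {self.tier!r}")
        if self.tier == "exact" and self.count != int(self.count):
            raise ValueError("exact counts must be integral")


class AsymptoticUnreliable(RuntimeError):
    """Asymptotic correction terms dominate the prefactor; estimate refused."""


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def falling_factorial_sums(k: Sequence[int], r: int) -> int:
    """M_r = sum_i k_i (k_i - 1) ... (k_i - r + 1)."""
    if r < 1:
        raise ValueError("r must be >= 1")
    total = 0
    for ki in k:
        term = 1
        for step in range(r):
            term *= ki - step
        if ki >= r:
            total += term
    return total


def log_asymptotic_count(k: Sequence[int]) -> float:
    """Natural log of the asymptotic count G of loop-free multigraphs with
    degree sequence ``k`` (all nonloop bond orders allowed, no loops).

    Prefactor M! / ((M/2)! 2^(M/2) k_1! ... k_n!) times exp of the five
    correction terms in M_2, M_3 with the loop/multiplicity indicators fixed
    to x_i = 1, y_i = 0; the O(k_max^3 / M) remainder is dropped.  Evaluated
    in log space for overflow safety.
    """
    m = falling_factorial_sums(k, 1)
    if m % 2 != 0:
        raise ValueError("degree sum must be even")
    m2 = falling_factorial_sums(k, 2)
    m3 = falling_factorial_sums(k, 3)
    logpref = (
        math.lgamma(m + 1)
        - math.lgamma(m // 2 + 1)
        - (m / 2) * math.log(2)
        - sum(math.lgamma(ki + 1) for ki in k)
    )
    # x_i = 1, y_i = 0:  y1 - 1/2 = -1/2;  x2 - 1/2 = 1/2;  x3 - x2 + 1/3 = 1/3
    corr = (
        -0.5 * m2 / m
        + 0.25 * m2**2 / m**2
        + 0.25 * m2**4 / m**5
        - 0.5 * m2**2 * m3 / m**4
        + m3**2 / (6 * m**3)
    )
    return logpref + corr


def asymptotic_count(
    k: Sequence[int], guard: float | None = 0.5, force: bool = False
) -> float:
    """G from the asymptotic law; refuses (unless ``force``) when the
    correction terms exceed ``guard`` times the log prefactor, the regime the
    relation is not calibrated for."""
    m = falling_factorial_sums(k, 1)
    if m % 2 != 0:
        raise ValueError("degree sum must be even")
    m2 = falling_factorial_sums(k, 2)
    m3 = falling_factorial_sums(k, 3)
    logpref = (
        math.lgamma(m + 1)
        - math.lgamma(m // 2 + 1)
        - (m / 2) * math.log(2)
        - sum(math.lgamma(ki + 1) for ki in k)
    )
    corr = log_asymptotic_count(k) - logpref
    if guard is not None and not force:
        if abs(corr) > max(1.0, guard * abs(logpref)):
            raise AsymptoticUnreliable(
                f"correction terms ({corr:.2f}) dominate the log prefactor "
                f"({logpref:.2f}); pass force=True to override"
            )
    return math.exp(log_asymptotic_count(k))


def hydrogen_correction(g: float, t: int) -> float:
    """Divide an asymptotic count by t! (overestimate from adding t
    monovalent atoms to a fixed heavy-atom profile)."""
    if t < 0:
        raise ValueError("t must be nonnegative")
    return g / math.factorial(t)


def monovalent_excess(d: LabeledDegreeSequence) -> int:
    """t: monovalent atoms beyond the least-hydrogenated realizable formula
    with the same heavy-atom (valence >= 2) profile."""
    heavy = [v for v in d.degrees if v >= 2]
    mono = sum(1 for v in d.degrees if v == 1)
    heavy_sum = sum(heavy)
    m = heavy_sum % 2  # parity of monovalent count needed for even degree sum
    while m <= mono:
        if is_realizable(heavy + [1] * m):
            return mono - m
        m += 2
    return 0


def nonpure_multiplier(d: LabeledDegreeSequence) -> int:
    """N_P(d): combinatorial count multiplier of a nonpure sequence over its
    pure counterpart (1 for pure sequences)."""
    out = 1
    for v, counts in d.per_valence().items():
        remaining = sum(counts)
        for c in counts:
            out *= math.comb(remaining, c)
            remaining -= c
    return out


def nonpure_path_length(d: LabeledDegreeSequence, l_g_pure: float) -> float:
    """l_G(d) = (1 + ln N_P(d) / sum_i d_i) * l_G(d_U)."""
    if l_g_pure < 0:
        raise ValueError("l_G must be nonnegative")
    return (1.0 + math.log(nonpure_multiplier(d)) / d.degree_sum) * l_g_pure


def count_from_path_length(
    l_g: float, cal: CalibrationConstants = DEFAULT_CALIBRATION
) -> float:
    """|U(d)| = exp(a7 * l_G + b7); strictly increasing in l_G."""
    if l_g < 0:
        raise ValueError("l_G must be nonnegative")
    return math.exp(cal.a7 * l_g + cal.b7)


def path_length_from_asymptotic(
    log_g: float, cal: CalibrationConstants = DEFAULT_CALIBRATION
) -> float:
    """l_G from the calibrated asymptotic line, clipped at 0."""
    return max(0.0, cal.a10 * log_g + cal.b10)


# ---------------------------------------------------------------------------
# measuring the average path length
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PathLengthEstimate:
    value: float
    stderr: float
    n_pairs: int
    running_mean: tuple[float, ...] = ()


def average_path_length(
    d: LabeledDegreeSequence,
    n_pairs: int | None = None,
    seed: int = 0,
    se_target: float = 0.05,
    max_pairs: int = 60,
    distance_budget=None,
) -> PathLengthEstimate:
    """Mean pairwise edit distance between random protomolecules of ``d``.

    Pairs come from independent, well-separated MCMC draws; pairs whose two
    members are isomorphic are skipped (distinct-pair sampling).  Sampling is
    adaptive: batches are added until the running mean's standard error drops
    below ``se_target`` of the mean or ``max_pairs`` is reached.  A universe
    with a single protomolecule has l_G = 0 by convention.
    """
    from .sampler import SamplerConfig, sample_graphs  # lazy: avoid cycle
    from .distance import LIGHT_BUDGET, edit_distance

    if not is_realizable(d.degrees):
        raise ValueError(f"degree sequence {d.key} is not realizable")
    if distance_budget is None:
        distance_budget = LIGHT_BUDGET
    if n_pairs is not None:
        max_pairs = n_pairs
        se_target = 0.0

    # class-level correction on: l_G averages over universe vertices, i.e.
    # isomorphism classes, not labeled realizations
    cfg = SamplerConfig(seed=seed, automorphism_correction=True)
    dists: list[float] = []
    running: list[float] = []
    batch = 8
    skipped = 0
    while len(dists) < max_pairs:
        want = min(batch, max_pairs - len(dists))
        samples = sample_graphs(
            d, 2 * want, replace(cfg, seed=seed + 1000 + len(dists) + skipped)
        )
        for i in range(0, len(samples) - 1, 2):
            g1, g2 = samples[i].graph, samples[i + 1].graph
            if g1.canonical_key == g2.canonical_key:
                skipped += 1
                continue
            est = edit_distance(
                g1, g2, budget=distance_budget, seed=seed + len(dists)
            )
            dists.append(est.value)
            running.append(float(np.mean(dists)))
        if skipped >= 4 * max_pairs and not dists:
            # all draws isomorphic: single-graph universe
            return PathLengthEstimate(0.0, 0.0, 0, ())
        if len(dists) >= 2 * batch and se_target > 0:
            se = np.std(dists, ddof=1) / math.sqrt(len(dists))
            if se < se_target * max(np.mean(dists), 1e-12):
                break
    if not dists:
        return PathLengthEstimate(0.0, 0.0, 0, ())
    mean = float(np.mean(dists))
    se = float(np.std(dists, ddof=1) / math.sqrt(len(dists))) if len(dists) > 1 else 0.0
    return PathLengthEstimate(mean, se, len(dists), tuple(running))


# ---------------------------------------------------------------------------
# tier dispatch
# ---------------------------------------------------------------------------

def estimate_count(
    d: LabeledDegreeSequence,
    db: "dict[str, CountRecord] | None" = None,
    cal: CalibrationConstants = DEFAULT_CALIBRATION,
    exact_cap: int = DEFAULT_ATOM_CAP,
    measure_cap: int = 30,
    seed: int = 0,
) -> CountRecord:
    """Best-available count of |U(d)|, cascading exact -> base -> pure ->
    asymptotic.

    The cascade: exact enumeration within ``exact_cap`` atoms (or a stored
    exact record); a stored measured l_G for d itself (base); a stored or
    freshly measured l_G for the pure counterpart stretched by the nonpure
    relations (pure; measuring allowed up to ``measure_cap`` atoms); finally
    the calibrated asymptotic law with the t! correction (asymptotic).
    """
    db = db or {}
    if not is_realizable(d.degrees):
        return CountRecord(key=d.key, tier="exact", count=0, note="unrealizable")

    stored = db.get(d.key)
    if stored is not None and stored.tier == "exact":
        return stored
    if d.natoms <= exact_cap:
        n = count_exact(d, cap=exact_cap)
        return CountRecord(key=d.key, tier="exact", count=n, note="enumerated")

    if stored is not None and stored.l_G is not None:
        return CountRecord(
            key=d.key,
            tier="base",
            count=count_from_path_length(stored.l_G, cal),
            l_G=stored.l_G,
            n_pairs=stored.n_pairs,
            seed=stored.seed,
            note="stored l_G",
        )

    du = d.pure_counterpart()
    pure_rec = db.get(du.key)
    l_pure: float | None = None
    n_pairs = 0
    note = ""
    if pure_rec is not None and pure_rec.l_G is not None:
        l_pure, n_pairs, note = pure_rec.l_G, pure_rec.n_pairs, "stored pure l_G"
    elif d.natoms <= measure_cap:
        est = average_path_length(du, seed=seed)
        l_pure, n_pairs, note = est.value, est.n_pairs, "measured pure l_G"
    if l_pure is not None:
        if du.key == d.key:  # d itself pure: plain base-style estimate
            return CountRecord(
                key=d.key,
                tier="base",
                count=count_from_path_length(l_pure, cal),
                l_G=l_pure,
                n_pairs=n_pairs,
                seed=seed,
                note=note,
            )
        l_g = nonpure_path_length(d, l_pure)
        return CountRecord(
            key=d.key,
            tier="pure",
            count=count_from_path_length(l_g, cal),
            l_G=l_g,
            n_pairs=n_pairs,
            seed=seed,
            note=note,
        )

    log_g = log_asymptotic_count(du.degrees)
    t = monovalent_excess(du)
    log_g -= math.lgamma(t + 1)
    l_pure = path_length_from_asymptotic(log_g, cal)
    l_g = nonpure_path_length(d, l_pure)
    return CountRecord(
        key=d.key,
        tier="asymptotic",
        count=count_from_path_length(l_g, cal),
        l_G=l_g,
        seed=seed,
        note=f"asymptotic, t={t}",
    )


# ---------------------------------------------------------------------------
# calibration refits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationRecord:
    d: LabeledDegreeSequence
    count: float
    l_G: float


@dataclass(frozen=True)
class CalibrationFit:
    constants: CalibrationConstants
    r2_count: float
    r2_asymptotic: float | None
    n_count: int
    n_asymptotic: int


def refit_calibration(
    records: Iterable[CalibrationRecord],
    min_records: int = 10,
    min_orders: float = 2.0,
) -> CalibrationFit:
    """Refit both calibrated lines from local exact data.

    Fits ln(count) on l_G (base-tier line) over all records with count >= 1,
    and l_G on ln(G) (asymptotic line) over the pure-sequence subset.  The
    inputs must span enough dynamic range for the fit to be meaningful
    (``min_records`` records over ``min_orders`` decades of counts).
    """
    recs = [r for r in records if r.count >= 1]
    if len(recs) < min_records:
        raise ValueError(f"need at least {min_records} usable records")
    counts = np.array([r.count for r in recs], dtype=float)
    span = math.log10(counts.max() / counts.min()) if counts.min() > 0 else 0
    if span < min_orders:
        raise ValueError(
            f"counts span only {span:.2f} orders of magnitude "
            f"(need {min_orders})"
        )
    lg = np.array([r.l_G for r in recs], dtype=float)
    if np.allclose(lg, lg[0]):
        raise ValueError("degenerate (constant) path-length predictor")
    fit7 = stats.linregress(lg, np.log(counts))

    pure = [r for r in recs if r.d.pure]
    a10, b10, r2_10, n10 = DEFAULT_CALIBRATION.a10, DEFAULT_CALIBRATION.b10, None, 0
    if len(pure) >= 3:
        logg = np.array([log_asymptotic_count(r.d.degrees) for r in pure])
        lgp = np.array([r.l_G for r in pure])
        if not np.allclose(logg, logg[0]):
            fit10 = stats.linregress(logg, lgp)
            if fit10.slope > 0:
                a10, b10 = float(fit10.slope), float(fit10.intercept)
                r2_10, n10 = float(fit10.rvalue**2), len(pure)

    constants = CalibrationConstants(
        a7=float(fit7.slope), b7=float(fit7.intercept), a10=a10, b10=b10
    )
    return CalibrationFit(
        constants=constants,
        r2_count=float(fit7.rvalue**2),
        r2_asymptotic=r2_10,
        n_count=len(recs),
        n_asymptotic=n10,
    )
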