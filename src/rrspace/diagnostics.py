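"""Uniformity validation of the sampler on exactly enumerable universes.

Two complementary views, both normalized so perfectly uniform sampling sits
at frequency 1:

* the sorted per-class frequency curve — uniform multinomial sampling gives a
  characteristic s-shaped curve that flattens with sample size; pointwise
  order-statistic envelopes are simulated under the uniform null at the same
  sample size, so a sampler whose curve leaves the envelope is biased (or the
  universe enumeration is wrong);
* per-stoichiometry frequencies divided by the stoichiometry's share of the
  universe — a weighted-selection bug shows up as ratios away from 1.

A chi-square goodness-of-fit against the uniform law accompanies the curves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class UniformityReport:
    n_classes: int
    n_samples: int
    sorted_frequencies: np.ndarray  # ascending, normalized (uniform -> 1)
    envelope_low: np.ndarray
    envelope_high: np.ndarray
    chi2: float
    p_value: float

    @property
    def inside_envelope(self) -> bool:
        return bool(
            np.all(self.sorted_frequencies >= self.envelope_low - 1e-12)
            and np.all(self.sorted_frequencies <= self.envelope_high + 1e-12)
        )


def sorted_frequency_curve(
    sample_keys: Sequence[str],
    universe_keys: Sequence[str],
    n_envelope: int = 1000,
    envelope_level: float = 0.99,
    seed: int = 0,
) -> UniformityReport:
    """Sorted normalized class frequencies with a simulated uniform envelope.

    ``universe_keys`` must cover the whole enumerated universe; a sample key
    outside it is a hard failure (it signals a sampler or enumeration bug,
    not bad luck).  The envelope holds, pointwise, the central
    ``envelope_level`` mass of the sorted-frequency order statistics of
    ``n_envelope`` simulated uniform multinomial draws of the same size.
    """
    universe = list(dict.fromkeys(universe_keys))
    k = len(universe)
    index = {key: i for i, key in enumerate(universe)}
    counts = np.zeros(k)
    for key in sample_keys:
        if key not in index:
            raise ValueError(
                "sample outside the enumerated universe "
                f"(key prefix {key[:40]!r}...)"
            )
        counts[index[key]] += 1
    n = int(counts.sum())
    if n == 0:
        raise ValueError("no samples")
    norm = n / k  # uniform expectation per class
    sorted_freq = np.sort(counts) / norm

    rng = np.random.default_rng(seed)
    sims = rng.multinomial(n, np.full(k, 1.0 / k), size=n_envelope)
    sims = np.sort(sims, axis=1) / norm
    alpha = (1.0 - envelope_level) / 2.0
    low = np.quantile(sims, alpha, axis=0)
    high = np.quantile(sims, 1.0 - alpha, axis=0)

    chi2, p = stats.chisquare(counts)
    return UniformityReport(
        n_classes=k,
        n_samples=n,
        sorted_frequencies=sorted_freq,
        envelope_low=low,
        envelope_high=high,
        chi2=float(chi2),
        p_value=float(p),
    )


def stoichiometry_frequency(
    sample_stoich_keys: Sequence[str],
    space_counts: Mapping[str, float],
) -> dict[str, float]:
    """Per-stoichiometry sampling frequency normalized by the stoichiometry's
    share of the universe; uniform sampling gives values ~= 1 everywhere."""
    total_count = float(sum(space_counts.values()))
    if total_count <= 0:
        raise ValueError("space counts must have positive total")
    n = len(sample_stoich_keys)
    if n == 0:
        raise ValueError("no samples")
    freq: dict[str, int] = {}
    for key in sample_stoich_keys:
        freq[key] = freq.get(key, 0) + 1
    out = {}
    for key, cnt in space_counts.items():
        share = cnt / total_count
        out[key] = (freq.get(key, 0) / n) / share if share > 0 else float("nan")
    return out
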