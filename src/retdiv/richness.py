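"""Chao1 species richness estimation and its aggregation at two spatial scales.

Observed richness undercounts true richness when sampling is incomplete.
Chao1 corrects the observed count upward using the numbers of species
represented by exactly one (f1, singletons) or two (f2, doubletons)
individuals, on the premise that rare species carry most of the information
about species missed entirely:

* classic:          S_hat = S_obs + f1^2 / (2 f2)            (f2 > 0)
* bias-corrected:   S_hat = S_obs + f1 (f1 - 1) / (2 (f2 + 1))

The bias-corrected form is the default (it is defined for f2 = 0 and is the
form common richness software falls back to); the classic form falls back to
the bias-corrected term when f2 = 0, with the unit flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import pandas as pd

from retdiv.capture_data import AbundanceTally

Variant = Literal["classic", "bias_corrected"]


@dataclass(frozen=True)
class ChaoEstimate:
    """Chao1 estimate with its sufficient statistics."""

    s_obs: int
    f1: int
    f2: int
    estimate: float
    variant: Variant
    #: True when the classic variant fell back to the bias-corrected term (f2=0).
    fallback: bool = False

    def __post_init__(self) -> None:
        if self.estimate < self.s_obs - 1e-9:
            raise ValueError("Chao1 estimate cannot fall below observed richness")
        if self.f1 + self.f2 > self.s_obs:
            raise ValueError("f1 + f2 cannot exceed observed richness")


def chao1(tally: AbundanceTally, variant: Variant = "bias_corrected") -> ChaoEstimate:
    """Chao1 richness estimate for one unit's abundance tally.

    An empty tally yields estimate 0.  Counts of zero are ignored (a species
    with no individuals in the unit is simply absent).
    """
    if variant not in ("classic", "bias_corrected"):
        raise ValueError(f"unknown variant {variant!r}")
    counts = [c for c in tally.counts.values() if c > 0]
    if any(c < 0 for c in tally.counts.values()):
        raise ValueError("negative counts")
    s_obs = len(counts)
    f1 = sum(1 for c in counts if c == 1)
    f2 = sum(1 for c in counts if c == 2)
    if s_obs == 0:
        return ChaoEstimate(0, 0, 0, 0.0, variant)
    fallback = False
    if variant == "classic":
        if f2 > 0:
            est = s_obs + f1 * f1 / (2.0 * f2)
        else:
            # standard practice: bias-corrected term when no doubletons
            est = s_obs + f1 * (f1 - 1) / 2.0
            fallback = True
    else:
        est = s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
    return ChaoEstimate(s_obs, f1, f2, est, variant, fallback)


def richness_by_scale(
    tallies: Iterable[AbundanceTally],
    species_filter: set[str] | None = None,
    variant: Variant = "bias_corrected",
) -> pd.DataFrame:
    """Per-unit richness response table for the mixed models.

    One row per unit with observed richness, the Chao1 estimate, and the unit
    covariates carried in each tally's metadata (treatment, year, week, and
    cover type where the tally is at the cover-type scale).  Species outside
    ``species_filter`` are dropped before estimation; rows are independent
    across scales (Chao1 is not additive, so no stand-vs-cover-type ordering
    is implied or asserted).
    """
    rows = []
    for tally in tallies:
        counts = dict(tally.counts)
        if species_filter is not None:
            counts = {s: c for s, c in counts.items() if s in species_filter}
        filtered = AbundanceTally(unit=tally.unit, counts=counts, meta=tally.meta)
        est = chao1(filtered, variant=variant)
        row = {
            "unit": tally.unit,
            "s_obs": est.s_obs,
            "f1": est.f1,
            "f2": est.f2,
            "chao1": est.estimate,
            "chao1_fallback": est.fallback,
            "n_individuals": filtered.total,
        }
        for key in ("block", "stand", "treatment", "year", "week", "cover_type"):
            if key in tally.meta:
                row[key] = tally.meta[key]
        rows.append(row)
    return pd.DataFrame(rows)
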