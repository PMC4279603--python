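"""Copy numbers -> GMO percentage.

One combination of wells is quantified as the ratio of mean copy numbers
(mean transgene copies over the chosen wells divided by mean reference-gene
copies), times 100, times a material-specific conversion factor that absorbs
the zygosity / copy-ratio-to-mass-fraction approximation.  Ratio of means —
not mean of per-well ratios — because transgene and reference wells are
unpaired on this plate design; it also makes the all-wells case collapse to a
single value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

POLICY_EXCLUDE = "exclude"
POLICY_ZERO = "zero_copies"


class QuantificationError(ValueError):
    pass


@dataclass(frozen=True)
class ConversionConfig:
    """factor: multiplicative zygosity/approximation correction (>0).
    missing_cq_policy: how undetermined sample wells enter the resampling pool
    — ``exclude`` drops them, ``zero_copies`` counts them as 0 copies."""

    factor: float = 1.0
    missing_cq_policy: str = POLICY_EXCLUDE

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise QuantificationError("conversion factor must be > 0")
        if self.missing_cq_policy not in (POLICY_EXCLUDE, POLICY_ZERO):
            raise QuantificationError(
                f"unknown missing_cq_policy {self.missing_cq_policy!r}"
            )


def combination_gmo_percent(
    tg_copies: Sequence[float],
    ref_copies: Sequence[float],
    config: ConversionConfig = ConversionConfig(),
) -> float:
    """GMO % = factor * mean(tg_copies) / mean(ref_copies) * 100."""
    tg = np.asarray(tg_copies, dtype=float)
    ref = np.asarray(ref_copies, dtype=float)
    if tg.size == 0 or ref.size == 0:
        raise QuantificationError("empty copy-number list after policy application")
    ref_mean = ref.mean()
    if ref_mean == 0:
        raise QuantificationError("mean reference-gene copies is 0: ratio undefined")
    return float(config.factor * tg.mean() / ref_mean * 100.0)
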