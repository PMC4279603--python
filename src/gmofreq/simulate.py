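"""Synthetic plates with known ground truth.

Emulates the Cq-level behaviour of a full 96-well GMO quantification plate at
low GM content: per gene a five-point triplicate standard curve, one NTC and
32 sample wells in two isolations of 16.  The generative model per sample
well is

    copies ~ Poisson(nominal mean)          (optional; the low-copy mechanism)
    Cq     = slope*log10(copies) + intercept
             + isolation effect + well noise [+ per-setting jitter]

At 0.1 % GM content with ~20000 reference copies per reaction the transgene
sees only ~20 template copies per well; Poisson sampling of the template is
what produces the strong right-skew of low-replicate GMO-percentage
distributions — Gaussian Cq noise alone cannot.  The isolation effect is one
Cq shift per DNA isolation, shared by both genes (a concentration effect of
the extraction).  Additional baseline/threshold settings are emulated as
small independent per-well Cq perturbations of the same underlying run, not
as independent plates.  Poisson draws of 0 copies yield undetermined Cq,
exercising the missing-Cq policy downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .plate import (
    GENES,
    REFERENCE,
    TRANSGENE,
    PlateExperiment,
    PlateLayout,
    WellRecord,
)


class SimulationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Ground truth and noise structure of a synthetic plate.

    Units: copies are template copies per reaction; all noise SDs are in
    cycles.  Defaults describe a realistic 0.1 % certified reference material
    measured with well-behaved assays (slope -3.3219 = perfect doubling;
    0.2 cycles well-to-well Cq scatter).
    """

    true_gmo_percent: float = 0.1
    ref_copies_per_reaction: float = 20000.0
    tg_slope: float = -3.3219
    tg_intercept: float = 37.0
    ref_slope: float = -3.3219
    ref_intercept: float = 37.0
    cq_noise_sd: float = 0.2
    isolation_effect_sd: float = 0.1
    poisson_template: bool = True
    n_pseudo_settings: int = 5
    setting_jitter_sd: float = 0.05
    standard_levels: tuple[float, ...] = (1e5, 1e4, 1e3, 1e2, 1e1)
    conversion_factor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cq_noise_sd", "isolation_effect_sd", "setting_jitter_sd"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")
        if self.true_gmo_percent <= 0 or self.ref_copies_per_reaction <= 0:
            raise SimulationError("GM content and reference copies must be > 0")
        if self.n_pseudo_settings < 1:
            raise SimulationError("need at least one pseudo-setting")

    @property
    def tg_copies_per_reaction(self) -> float:
        """Nominal transgene template copies implied by the ground truth."""
        return (
            self.ref_copies_per_reaction
            * self.true_gmo_percent
            / 100.0
            / self.conversion_factor
        )

    def curve(self, gene: str) -> tuple[float, float]:
        if gene == TRANSGENE:
            return self.tg_slope, self.tg_intercept
        return self.ref_slope, self.ref_intercept


def simulate_plate(config: SimulationConfig) -> PlateExperiment:
    """Generate a PlateExperiment; bit-identical for a fixed seed.

    Setting ``setting_1`` carries the base Cq values; every further
    pseudo-setting adds independent N(0, setting_jitter_sd) per-well jitter on
    top of the same base values.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    layout = PlateLayout.default_96well(
        standard_levels=config.standard_levels,
        nominal_gmo_percent=config.true_gmo_percent,
        conversion_factor=config.conversion_factor,
    )

    # one concentration-like Cq shift per DNA isolation, shared by both genes
    iso_effect = rng.normal(0.0, config.isolation_effect_sd, size=2)

    base_cq: dict[str, float | None] = {}
    for gene in GENES:
        slope, intercept = config.curve(gene)
        gl = layout.genes[gene]
        for pos, copies in gl.standards.items():
            base_cq[pos] = (
                slope * math.log10(copies)
                + intercept
                + rng.normal(0.0, config.cq_noise_sd)
            )
        for pos in gl.ntc:
            base_cq[pos] = None
        mean_copies = (
            config.tg_copies_per_reaction
            if gene == TRANSGENE
            else config.ref_copies_per_reaction
        )
        for pos in sorted(gl.samples, key=lambda p: (gl.samples[p], p)):
            iso = gl.samples[pos]
            if config.poisson_template:
                template = float(rng.poisson(mean_copies))
            else:
                template = mean_copies
                if template <= 0:
                    raise SimulationError(
                        "non-positive template copies without Poisson sampling"
                    )
            if template == 0:
                base_cq[pos] = None
            else:
                base_cq[pos] = (
                    slope * math.log10(template)
                    + intercept
                    + iso_effect[iso - 1]
                    + rng.normal(0.0, config.cq_noise_sd)
                )

    positions = layout.all_positions
    settings: dict[str, list[WellRecord]] = {}
    # position -> (gene, task, copies, iso) lookup for record construction
    meta: dict[str, tuple[str, str, float | None, int | None]] = {}
    for gene, gl in layout.genes.items():
        for p, c in gl.standards.items():
            meta[p] = (gene, "standard", c, None)
        for p in gl.ntc:
            meta[p] = (gene, "ntc", None, None)
        for p, iso in gl.samples.items():
            meta[p] = (gene, "sample", None, iso)

    for s in range(1, config.n_pseudo_settings + 1):
        jitter = (
            rng.normal(0.0, config.setting_jitter_sd, size=len(positions))
            if s > 1
            else np.zeros(len(positions))
        )
        records = []
        for pos, dj in zip(positions, jitter):
            gene, task, copies, iso = meta[pos]
            cq = base_cq[pos]
            records.append(
                WellRecord(
                    position=pos,
                    gene=gene,
                    task=task,
                    cq=None if cq is None else float(cq + dj),
                    known_copies=copies,
                    isolation_id=iso,
                )
            )
        settings[f"setting_{s}"] = records
    return PlateExperiment(layout=layout, settings=settings)
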