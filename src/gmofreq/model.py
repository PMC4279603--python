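"""Model/Results interface over the whole pipeline.

``PlateVariabilityModel`` holds a plate experiment plus the analysis
parameters; ``fit(seed)`` fits the per-(setting, gene) standard curves,
builds (or reuses) the shared resampling plan, evaluates every replicate
setting into its GMO-percentage population, and summarises the grid.  The
returned ``PlateVariabilityResults`` carries the curves, plan, populations
and per-cell statistics, exposes ``summary()`` as a DataFrame and the plots.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .calibration import StandardCurve, fit_curve_from_records, validate_ntc
from .plate import (
    GENES,
    PlateExperiment,
    PlateLayout,
    assemble_experiment,
    parse_plate_export,
)
from .quantify import ConversionConfig
from .resampling import (
    DEFAULT_KS,
    DEFAULT_N_COMBINATIONS,
    GmoPopulation,
    ResamplingPlan,
    build_plan,
    compute_copies,
    evaluate_plan,
    pools_from_experiment,
)
from .stats import (
    DEFAULT_COVERAGE,
    DEFAULT_N_CLASSES,
    DEFAULT_RSD_THRESHOLD,
    SweepCell,
    min_replicates_for_rsd,
    replicate_sweep,
    summary_table,
)


class PlateVariabilityModel:
    """Intra-plate measurement-variability analysis of one qPCR plate.

    Parameters
    ----------
    experiment
        The plate layout plus one Cq table per baseline/threshold setting.
    ks
        Replicate numbers k of the 2xk ladder (k wells per isolation).
    n_combinations
        Random well combinations per replicate setting (population size).
    n_classes, coverage_target
        Histogram classes and the cut-off share of values.
    rsd_threshold
        Relative-SD criterion (%) for the minimum-replicates recommendation.
    conversion
        Conversion factor and missing-Cq policy; defaults to the layout's
        conversion factor with policy ``exclude``.
    nominal
        Certified GM content (%); defaults to the layout's value.
    chi_df
        Chi-square degrees of freedom; default n_classes - 3.
    ntc_max_cq
        If set, NTC wells may amplify beyond this Cq; otherwise any NTC
        amplification is an error.
    """

    def __init__(
        self,
        experiment: PlateExperiment,
        ks: Sequence[int] = DEFAULT_KS,
        n_combinations: int = DEFAULT_N_COMBINATIONS,
        n_classes: int = DEFAULT_N_CLASSES,
        coverage_target: float = DEFAULT_COVERAGE,
        rsd_threshold: float = DEFAULT_RSD_THRESHOLD,
        conversion: ConversionConfig | None = None,
        nominal: float | None = None,
        chi_df: int | None = None,
        ntc_max_cq: float | None = None,
    ) -> None:
        self.experiment = experiment
        self.ks = tuple(sorted(set(int(k) for k in ks)))
        self.n_combinations = int(n_combinations)
        self.n_classes = int(n_classes)
        self.coverage_target = float(coverage_target)
        self.rsd_threshold = float(rsd_threshold)
        self.conversion = conversion or ConversionConfig(
            factor=experiment.layout.conversion_factor
        )
        self.nominal = (
            float(nominal) if nominal is not None else experiment.layout.nominal_gmo_percent
        )
        self.chi_df = chi_df
        self.ntc_max_cq = ntc_max_cq

    # ------------------------------------------------------------ constructors

    @classmethod
    def from_files(
        cls,
        layout_path: str | Path,
        setting_files: Mapping[str, str | Path],
        **kwargs,
    ) -> "PlateVariabilityModel":
        """Build from a layout YAML and one canonical Cq table per setting."""
        layout = PlateLayout.from_yaml(layout_path)
        tables = {
            sid: parse_plate_export(path, layout) for sid, path in setting_files.items()
        }
        return cls(assemble_experiment(layout, tables), **kwargs)

    @classmethod
    def from_simulation(cls, sim_config, **kwargs) -> "PlateVariabilityModel":
        """Build from a synthetic plate (see :mod:`gmofreq.simulate`)."""
        from .simulate import simulate_plate

        return cls(simulate_plate(sim_config), **kwargs)

    # ------------------------------------------------------------------- fit

    def fit(self, seed: int = 0, plan: ResamplingPlan | None = None) -> "PlateVariabilityResults":
        """Run calibration, resampling and statistics; deterministic given
        ``seed`` (or an explicit pre-built ``plan``)."""
        for sid in self.experiment.setting_ids:
            validate_ntc(self.experiment.records(sid), max_cq=self.ntc_max_cq)
        curves: dict[tuple[str, str], StandardCurve] = {}
        for sid in self.experiment.setting_ids:
            for gene in GENES:
                curves[(sid, gene)] = fit_curve_from_records(
                    self.experiment.standard_records(sid, gene)
                )
        if plan is None:
            pools = pools_from_experiment(
                self.experiment, self.conversion, min_pool=max(self.ks)
            )
            plan = build_plan(
                pools, ks=self.ks, n_combinations=self.n_combinations, seed=seed
            )
        copies = compute_copies(self.experiment, curves, self.conversion)
        populations = evaluate_plan(plan, copies, self.conversion)
        grid = replicate_sweep(
            populations,
            nominal=self.nominal,
            n_classes=self.n_classes,
            coverage_target=self.coverage_target,
            chi_df=self.chi_df,
        )
        return PlateVariabilityResults(
            model=self, plan=plan, curves=curves, populations=populations, grid=grid
        )


@dataclass
class PlateVariabilityResults:
    """Fitted curves, the frozen plan, all populations, and the statistics
    grid of one plate analysis."""

    model: PlateVariabilityModel
    plan: ResamplingPlan
    curves: dict[tuple[str, str], StandardCurve]
    populations: list[GmoPopulation]
    grid: dict[tuple[str, int], SweepCell]

    def summary(self) -> pd.DataFrame:
        """One row per (setting, k): mean, SD, RSD, skewness, chi-square p
        (%), trueness, and the cut-off summary."""
        return summary_table(self.grid)

    def curve_table(self) -> pd.DataFrame:
        rows = []
        for (sid, gene), c in sorted(self.curves.items()):
            rows.append(
                {
                    "setting": sid,
                    "gene": gene,
                    "slope": c.slope,
                    "intercept": c.intercept,
                    "r_squared": c.r_squared,
                    "efficiency": c.efficiency,
                    "n_points": c.n_points,
                }
            )
        return pd.DataFrame(rows)

    def min_replicates(self, rsd_threshold: float | None = None) -> int | None:
        """Smallest k with RSD at or below the threshold in every setting."""
        thr = self.model.rsd_threshold if rsd_threshold is None else rsd_threshold
        return min_replicates_for_rsd(self.grid, rsd_threshold=thr)

    def population(self, setting_id: str, k: int) -> GmoPopulation:
        for pop in self.populations:
            if pop.setting_id == setting_id and pop.k == k:
                return pop
        raise KeyError((setting_id, k))

    # ------------------------------------------------------------------ plots

    def plot_histogram(self, setting_id: str, k: int, ax=None):
        from .plotting import histogram_figure

        return histogram_figure(
            self.grid[(setting_id, k)], nominal=self.model.nominal, ax=ax
        )

    def plot_grid(self, ks: Sequence[int] | None = None):
        from .plotting import grid_figure

        return grid_figure(self, ks=ks)

    def plot_rsd_curve(self, ax=None):
        from .plotting import rsd_curve_figure

        return rsd_curve_figure(self, ax=ax)
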