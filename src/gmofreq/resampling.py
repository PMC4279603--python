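"""Seeded random well combinations and their GMO-percentage populations.

The heart of the approach: for every replicate setting 2xk (k wells taken
from EACH of the two DNA isolations, per gene), build ``n_combinations``
random well combinations — by default 5000 — and evaluate each into one GMO
percentage.  The plan of well indices is created once from a root seed and
then reused for every baseline/threshold setting, so that the settings are
compared on the identical draws.

Within a combination, wells are drawn without replacement inside each
(gene, isolation) pool; across the 5000 combinations, draws are independent
(repeats may occur — exhaustive enumeration is intractable already at k = 8,
C(16,8)^4 ≈ 2.8e16).  Per-k substreams are derived from the root seed with
``numpy.random.SeedSequence(seed, spawn_key=(k,))``, a stable documented
scheme that allows partial re-runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .plate import GENES, PlateExperiment, well_sort_key
from .quantify import POLICY_EXCLUDE, POLICY_ZERO, ConversionConfig, QuantificationError

PoolKey = tuple[str, int]  # (gene, isolation_id)

#: canonical pool order used everywhere (streams, exports)
POOL_ORDER: tuple[PoolKey, ...] = (
    ("transgene", 1),
    ("transgene", 2),
    ("reference", 1),
    ("reference", 2),
)

DEFAULT_N_COMBINATIONS = 5000
DEFAULT_KS = tuple(range(2, 17))


class ResamplingError(ValueError):
    pass


@dataclass
class ResamplingPlan:
    """The frozen well-index combinations, shared across settings.

    ``pools`` maps (gene, isolation) to the ordered list of well positions the
    indices refer to; ``combos[k][pool]`` is an (n_combinations, k) integer
    array of indices into that pool.
    """

    seed: int
    n_combinations: int
    ks: tuple[int, ...]
    pools: dict[PoolKey, list[str]]
    combos: dict[int, dict[PoolKey, np.ndarray]]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ResamplingPlan):
            return NotImplemented
        return (
            self.seed == other.seed
            and self.n_combinations == other.n_combinations
            and self.ks == other.ks
            and self.pools == other.pools
            and all(
                np.array_equal(self.combos[k][p], other.combos[k][p])
                for k in self.ks
                for p in POOL_ORDER
            )
        )


def build_plan(
    pools: Mapping[PoolKey, Sequence[str]],
    ks: Sequence[int] = DEFAULT_KS,
    n_combinations: int = DEFAULT_N_COMBINATIONS,
    seed: int = 0,
) -> ResamplingPlan:
    """Draw the combination plan; a pure function of its arguments.

    Each combination draws, for every (gene, isolation) pool, a uniform
    k-subset without replacement, independently across pools and combinations.
    """
    ks = tuple(sorted(set(int(k) for k in ks)))
    if not ks or ks[0] < 1:
        raise ResamplingError("replicate numbers must be >= 1")
    pools_ = {p: list(pools[p]) for p in POOL_ORDER}
    for key in POOL_ORDER:
        size = len(pools_[key])
        if max(ks) > size:
            gene, iso = key
            raise ResamplingError(
                f"k={max(ks)} exceeds pool size {size} for {gene} isolation {iso}"
            )
    combos: dict[int, dict[PoolKey, np.ndarray]] = {}
    for k in ks:
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(k,)))
        per_pool: dict[PoolKey, np.ndarray] = {}
        for key in POOL_ORDER:
            size = len(pools_[key])
            # uniform k-subsets: rank a uniform matrix, keep the first k ranks;
            # sorting within each subset makes equal subsets bit-identical
            # downstream (k = pool size then collapses to exactly one value)
            u = rng.random((n_combinations, size))
            per_pool[key] = np.sort(np.argsort(u, axis=1)[:, :k], axis=1)
        combos[k] = per_pool
    return ResamplingPlan(
        seed=seed, n_combinations=n_combinations, ks=ks, pools=pools_, combos=combos
    )


def pools_from_experiment(
    experiment: PlateExperiment,
    config: ConversionConfig = ConversionConfig(),
    min_pool: int | None = None,
) -> dict[PoolKey, list[str]]:
    """Sampling pools from the layout's sample wells.

    Under ``missing_cq_policy='exclude'`` a well undetermined in ANY setting is
    removed from its pool for ALL settings, so the shared plan stays valid
    across settings.  ``min_pool`` (typically max(ks)) guards against pools
    shrinking below the largest replicate number.
    """
    pools: dict[PoolKey, list[str]] = {}
    for gene in GENES:
        gl = experiment.layout.genes[gene]
        for iso in (1, 2):
            positions = gl.sample_positions(iso)
            if config.missing_cq_policy == POLICY_EXCLUDE:
                undetermined: set[str] = set()
                for sid in experiment.setting_ids:
                    rec = experiment.record_map(sid)
                    undetermined |= {p for p in positions if rec[p].cq is None}
                positions = [p for p in positions if p not in undetermined]
            pools[(gene, iso)] = positions
            if min_pool is not None and len(positions) < min_pool:
                raise ResamplingError(
                    f"pool for {gene} isolation {iso} has only {len(positions)} "
                    f"usable wells, fewer than the largest replicate number {min_pool}"
                )
    return pools


def compute_copies(
    experiment: PlateExperiment,
    curves: Mapping[tuple[str, str], "object"],
    config: ConversionConfig = ConversionConfig(),
) -> dict[str, dict[str, float]]:
    """Per setting, map sample-well position -> estimated copies.

    ``curves`` maps (setting_id, gene) to a fitted StandardCurve.  Undetermined
    wells are omitted under policy ``exclude`` and counted as 0 copies under
    ``zero_copies``.
    """
    out: dict[str, dict[str, float]] = {}
    for sid in experiment.setting_ids:
        per_setting: dict[str, float] = {}
        for gene in GENES:
            curve = curves[(sid, gene)]
            for r in experiment.sample_records(sid, gene):
                if r.cq is None:
                    if config.missing_cq_policy == POLICY_ZERO:
                        per_setting[r.position] = 0.0
                else:
                    per_setting[r.position] = curve.cq_to_copies(r.cq)
        out[sid] = per_setting
    return out


@dataclass
class GmoPopulation:
    """The n_combinations GMO-percentage values of one (setting, k) cell."""

    setting_id: str
    k: int
    values: np.ndarray


def evaluate_plan(
    plan: ResamplingPlan,
    copies_by_setting: Mapping[str, Mapping[str, float]],
    config: ConversionConfig = ConversionConfig(),
) -> list[GmoPopulation]:
    """Apply the SAME index tuples to every setting's copy numbers.

    Returns one population per (setting, k), in setting-major order.  Every
    well position a pool references must carry a copy number in every setting
    (pools are pre-shrunk for excluded wells at plan-build time).
    """
    populations: list[GmoPopulation] = []
    for sid, copies in copies_by_setting.items():
        pool_values: dict[PoolKey, np.ndarray] = {}
        for key in POOL_ORDER:
            try:
                pool_values[key] = np.array(
                    [copies[p] for p in plan.pools[key]], dtype=float
                )
            except KeyError as exc:
                gene, iso = key
                raise ResamplingError(
                    f"setting {sid!r}: no copy number for well {exc.args[0]} "
                    f"({gene} isolation {iso}); was the plan built for this plate?"
                ) from None
        for k in plan.ks:
            tg = np.concatenate(
                [
                    pool_values[("transgene", 1)][plan.combos[k][("transgene", 1)]],
                    pool_values[("transgene", 2)][plan.combos[k][("transgene", 2)]],
                ],
                axis=1,
            )
            ref = np.concatenate(
                [
                    pool_values[("reference", 1)][plan.combos[k][("reference", 1)]],
                    pool_values[("reference", 2)][plan.combos[k][("reference", 2)]],
                ],
                axis=1,
            )
            ref_mean = ref.mean(axis=1)
            if np.any(ref_mean == 0):
                raise QuantificationError(
                    f"setting {sid!r}, 2x{k}: a combination has mean reference "
                    "copies of 0; ratio undefined"
                )
            values = config.factor * tg.mean(axis=1) / ref_mean * 100.0
            populations.append(GmoPopulation(setting_id=sid, k=k, values=values))
    return populations


# ------------------------------------------------------------ plan (de)serialisation


def export_plan(plan: ResamplingPlan, path: str | Path) -> None:
    """Plain-text plan export (TSV) for audit and exact re-runs."""
    with open(path, "w") as fh:
        fh.write("# gmofreq-plan v1\n")
        fh.write(f"# seed={plan.seed}\n")
        fh.write(f"# n_combinations={plan.n_combinations}\n")
        fh.write(f"# ks={','.join(map(str, plan.ks))}\n")
        for gene, iso in POOL_ORDER:
            fh.write(f"# pool\t{gene}\t{iso}\t{','.join(plan.pools[(gene, iso)])}\n")
        fh.write("k\tcombination\t" + "\t".join(f"{g}_iso{i}" for g, i in POOL_ORDER) + "\n")
        for k in plan.ks:
            cols = [plan.combos[k][key] for key in POOL_ORDER]
            for i in range(plan.n_combinations):
                cells = [" ".join(map(str, col[i])) for col in cols]
                fh.write(f"{k}\t{i}\t" + "\t".join(cells) + "\n")


def import_plan(path: str | Path) -> ResamplingPlan:
    """Re-load an exported plan; round-trips bit-identically."""
    meta: dict[str, str] = {}
    pools: dict[PoolKey, list[str]] = {}
    rows: dict[int, dict[PoolKey, list[list[int]]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# pool\t"):
                _, gene, iso, wells = line[2:].split("\t")
                pools[(gene, int(iso))] = wells.split(",") if wells else []
            elif line.startswith("# ") and "=" in line:
                key, _, val = line[2:].partition("=")
                meta[key] = val
            elif line.startswith("#") or line.startswith("k\t"):
                continue
            else:
                parts = line.split("\t")
                k = int(parts[0])
                per_k = rows.setdefault(k, {key: [] for key in POOL_ORDER})
                for key, cell in zip(POOL_ORDER, parts[2:]):
                    per_k[key].append([int(t) for t in cell.split()])
    ks = tuple(int(t) for t in meta["ks"].split(","))
    combos = {
        k: {key: np.array(per_k[key], dtype=np.int64) for key in POOL_ORDER}
        for k, per_k in rows.items()
    }
    return ResamplingPlan(
        seed=int(meta["seed"]),
        n_combinations=int(meta["n_combinations"]),
        ks=ks,
        pools=pools,
        combos=combos,
    )
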