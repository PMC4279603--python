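"""Plate data model and I/O for qPCR Cq exports.

A single 96-well plate carries, for each of the two targets (event-specific
transgene and species-specific reference gene), a five-point standard curve in
triplicates, one no-template control, and 32 replicate wells of the sample DNA
split over two independent DNA isolations (16 + 16).  One physical run is
re-analysed under several instrument baseline/threshold settings; each setting
yields its own Cq table over the identical wells.

The canonical table format is a delimited text file (comma or tab) with a
header row and columns ``Well, Target, Task, Cq, Quantity``.  Wells without
amplification carry the explicit marker ``Undetermined`` (case-insensitive) or
an empty Cq field; they are preserved, never coerced to a number or dropped at
parse time.  Plate layout (which wells are standards/samples/NTC, isolation
membership, nominal GM content) is supplied as a YAML config, not inferred
from the export, because vendor exports do not encode isolation membership.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

TRANSGENE = "transgene"
REFERENCE = "reference"
GENES = (TRANSGENE, REFERENCE)

TASK_SAMPLE = "sample"
TASK_STANDARD = "standard"
TASK_NTC = "ntc"

#: canonical column order of the plate table
TABLE_COLUMNS = ("Well", "Target", "Task", "Cq", "Quantity")

_POSITION_RE = re.compile(r"^[A-H](?:[1-9]|1[0-2])$")
_UNDETERMINED_TOKENS = {"undetermined", "undet", "n/a", "na", ""}


class PlateError(ValueError):
    """Raised for malformed plate tables or layout configs."""


def is_valid_position(position: str) -> bool:
    """True for alphanumeric plate labels A1..H12."""
    return bool(_POSITION_RE.match(position))


def well_sort_key(position: str) -> tuple[int, int]:
    return (ord(position[0]) - ord("A"), int(position[1:]))


@dataclass(frozen=True)
class WellRecord:
    """One well of one setting's Cq table.

    ``cq is None`` encodes an undetermined (no amplification) well.
    ``known_copies`` is set for standards only, ``isolation_id`` (1 or 2)
    for sample wells only.
    """

    position: str
    gene: str
    task: str
    cq: float | None
    known_copies: float | None = None
    isolation_id: int | None = None

    def __post_init__(self) -> None:
        if not is_valid_position(self.position):
            raise PlateError(f"invalid well position {self.position!r}")
        if self.gene not in GENES:
            raise PlateError(f"unknown gene {self.gene!r}")
        if self.task not in (TASK_SAMPLE, TASK_STANDARD, TASK_NTC):
            raise PlateError(f"unknown task {self.task!r}")
        if self.task == TASK_STANDARD:
            if self.known_copies is None or self.known_copies <= 0:
                raise PlateError(
                    f"standard well {self.position} needs positive known_copies"
                )
        elif self.known_copies is not None:
            raise PlateError(f"known_copies only allowed on standards ({self.position})")
        if self.task == TASK_SAMPLE:
            if self.isolation_id not in (1, 2):
                raise PlateError(f"sample well {self.position} needs isolation_id 1 or 2")
        elif self.isolation_id is not None:
            raise PlateError(f"isolation_id only allowed on samples ({self.position})")
        if self.cq is not None and not self.cq > 0:
            raise PlateError(f"well {self.position}: Cq must be positive, got {self.cq}")

    @property
    def is_determined(self) -> bool:
        return self.cq is not None


@dataclass
class GeneLayout:
    """Wells of one target on the plate."""

    standards: dict[str, float]          # position -> nominal copies
    ntc: list[str]
    samples: dict[str, int]              # position -> isolation id (1 or 2)

    def sample_positions(self, isolation_id: int) -> list[str]:
        pos = [p for p, iso in self.samples.items() if iso == isolation_id]
        return sorted(pos, key=well_sort_key)

    @property
    def all_positions(self) -> list[str]:
        return list(self.standards) + list(self.ntc) + list(self.samples)


@dataclass
class PlateLayout:
    """Plate layout plus the analysis constants tied to the material.

    ``nominal_gmo_percent`` is the certified GM content of the reference
    material in %, ``conversion_factor`` the multiplicative zygosity /
    copy-ratio-to-mass-fraction correction (default 1: plain copy ratio).
    """

    genes: dict[str, GeneLayout]
    nominal_gmo_percent: float
    conversion_factor: float = 1.0

    def __post_init__(self) -> None:
        if set(self.genes) != set(GENES):
            raise PlateError(f"layout must define genes {GENES}, got {tuple(self.genes)}")
        if self.conversion_factor <= 0:
            raise PlateError("conversion_factor must be > 0")
        seen: set[str] = set()
        for gene, gl in self.genes.items():
            positions = gl.all_positions
            if len(positions) > 48:
                raise PlateError(f"{gene}: more than 48 wells assigned")
            for p in positions:
                if not is_valid_position(p):
                    raise PlateError(f"{gene}: invalid well position {p!r}")
                if p in seen:
                    raise PlateError(f"well {p} assigned twice in layout")
                seen.add(p)
            for iso in (1, 2):
                if not gl.sample_positions(iso):
                    raise PlateError(f"{gene}: isolation {iso} has no sample wells")
            for p, c in gl.standards.items():
                if c <= 0:
                    raise PlateError(f"standard {p}: copies must be > 0")

    @property
    def all_positions(self) -> list[str]:
        out: list[str] = []
        for gl in self.genes.values():
            out.extend(gl.all_positions)
        return sorted(out, key=well_sort_key)

    # ------------------------------------------------------------------ YAML

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PlateLayout":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "PlateLayout":
        try:
            genes = {}
            for gene in GENES:
                g = raw["genes"][gene]
                standards = {str(s["position"]): float(s["copies"]) for s in g["standards"]}
                ntc = [str(p) for p in g.get("ntc", [])]
                samples: dict[str, int] = {}
                for iso_key, iso_id in (("isolation1", 1), ("isolation2", 2)):
                    for p in g["samples"][iso_key]:
                        samples[str(p)] = iso_id
                genes[gene] = GeneLayout(standards=standards, ntc=ntc, samples=samples)
            return cls(
                genes=genes,
                nominal_gmo_percent=float(raw["nominal_gmo_percent"]),
                conversion_factor=float(raw.get("conversion_factor", 1.0)),
            )
        except (KeyError, TypeError) as exc:
            raise PlateError(f"malformed layout config: {exc!r}") from exc

    def to_dict(self) -> dict:
        return {
            "nominal_gmo_percent": self.nominal_gmo_percent,
            "conversion_factor": self.conversion_factor,
            "genes": {
                gene: {
                    "standards": [
                        {"position": p, "copies": c} for p, c in gl.standards.items()
                    ],
                    "ntc": list(gl.ntc),
                    "samples": {
                        "isolation1": gl.sample_positions(1),
                        "isolation2": gl.sample_positions(2),
                    },
                }
                for gene, gl in self.genes.items()
            },
        }

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    # ------------------------------------------------------- default layout

    @classmethod
    def default_96well(
        cls,
        standard_levels: Iterable[float] = (1e5, 1e4, 1e3, 1e2, 1e1),
        nominal_gmo_percent: float = 0.1,
        conversion_factor: float = 1.0,
    ) -> "PlateLayout":
        """The standard full-plate scheme: per gene 5 standard levels in
        triplicates (15 wells), 1 NTC, and 32 sample wells in two isolations
        of 16 (2x 48 - 2x 15 - 2x 1 = 2x 32).  Transgene occupies rows A-D,
        reference gene rows E-H.
        """
        levels = list(standard_levels)
        if len(levels) != 5:
            raise PlateError("default layout expects exactly 5 standard levels")

        def rows(first_row: str) -> list[str]:
            r0 = ord(first_row)
            return [f"{chr(r0 + i)}{j}" for i in range(4) for j in range(1, 13)]

        genes = {}
        for gene, first_row in ((TRANSGENE, "A"), (REFERENCE, "E")):
            wells = rows(first_row)
            standards = {wells[i]: levels[i // 3] for i in range(15)}
            ntc = [wells[15]]
            sample_wells = wells[16:48]
            samples = {p: (1 if i < 16 else 2) for i, p in enumerate(sample_wells)}
            genes[gene] = GeneLayout(standards=standards, ntc=ntc, samples=samples)
        return cls(
            genes=genes,
            nominal_gmo_percent=nominal_gmo_percent,
            conversion_factor=conversion_factor,
        )


@dataclass
class PlateExperiment:
    """One physical plate: a layout plus one Cq table per baseline/threshold
    setting.  All settings cover the identical wells; only Cq differs."""

    layout: PlateLayout
    settings: dict[str, list[WellRecord]] = field(default_factory=dict)

    @property
    def setting_ids(self) -> list[str]:
        return list(self.settings)

    def records(self, setting_id: str) -> list[WellRecord]:
        return self.settings[setting_id]

    def record_map(self, setting_id: str) -> dict[str, WellRecord]:
        return {r.position: r for r in self.settings[setting_id]}

    def standard_records(self, setting_id: str, gene: str) -> list[WellRecord]:
        return [r for r in self.settings[setting_id] if r.gene == gene and r.task == TASK_STANDARD]

    def sample_records(self, setting_id: str, gene: str) -> list[WellRecord]:
        return [r for r in self.settings[setting_id] if r.gene == gene and r.task == TASK_SAMPLE]


# --------------------------------------------------------------------- parse


def _parse_cq(raw, position: str) -> float | None:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return None
    text = str(raw).strip()
    if text.lower() in _UNDETERMINED_TOKENS:
        return None
    try:
        return float(text)
    except ValueError:
        raise PlateError(f"well {position}: unparseable Cq value {raw!r}") from None


def parse_plate_export(
    source: str | Path | io.IOBase, layout: PlateLayout
) -> list[WellRecord]:
    """Parse a canonical plate table against a layout.

    Every position the layout assigns must be present exactly once; target and
    task are cross-checked against the layout; undetermined Cq values are kept
    as explicit missing markers.  Missing or duplicated wells and unparseable
    Cq fields are hard errors naming the well.
    """
    df = pd.read_csv(source, sep=None, engine="python", dtype=str, skip_blank_lines=True)
    if df.empty:
        raise PlateError("no rows in plate export")
    cols = {c.strip().lower(): c for c in df.columns}
    for needed in ("well", "target", "task", "cq"):
        if needed not in cols:
            raise PlateError(f"plate export is missing column {needed!r}")

    # layout lookup: position -> (gene, task, known_copies, isolation)
    expected: dict[str, tuple[str, str, float | None, int | None]] = {}
    for gene, gl in layout.genes.items():
        for p, c in gl.standards.items():
            expected[p] = (gene, TASK_STANDARD, c, None)
        for p in gl.ntc:
            expected[p] = (gene, TASK_NTC, None, None)
        for p, iso in gl.samples.items():
            expected[p] = (gene, TASK_SAMPLE, None, iso)

    records: dict[str, WellRecord] = {}
    for _, row in df.iterrows():
        position = str(row[cols["well"]]).strip()
        if position in records:
            raise PlateError(f"duplicate well {position} in plate export")
        if position not in expected:
            raise PlateError(f"well {position} in export is not assigned in the layout")
        gene, task, copies, iso = expected[position]
        target = str(row[cols["target"]]).strip().lower()
        if target != gene:
            raise PlateError(
                f"well {position}: export target {target!r} contradicts layout ({gene})"
            )
        task_raw = str(row[cols["task"]]).strip().lower()
        if task_raw != task:
            raise PlateError(
                f"well {position}: export task {task_raw!r} contradicts layout ({task})"
            )
        if task == TASK_STANDARD and "quantity" in cols:
            q = row[cols["quantity"]]
            if q is not None and not pd.isna(q) and str(q).strip() != "":
                copies = float(q)
        records[position] = WellRecord(
            position=position,
            gene=gene,
            task=task,
            cq=_parse_cq(row[cols["cq"]], position),
            known_copies=copies,
            isolation_id=iso,
        )

    missing = sorted(set(expected) - set(records), key=well_sort_key)
    if missing:
        raise PlateError(f"plate export is missing layout wells: {', '.join(missing)}")
    return sorted(records.values(), key=lambda r: well_sort_key(r.position))


def write_plate_table(records: Iterable[WellRecord], path: str | Path) -> None:
    """Write records to the canonical CSV form (round-trips with
    :func:`parse_plate_export`)."""
    rows = []
    for r in sorted(records, key=lambda r: well_sort_key(r.position)):
        rows.append(
            {
                "Well": r.position,
                "Target": r.gene,
                "Task": r.task,
                "Cq": "Undetermined" if r.cq is None else repr(r.cq),
                "Quantity": "" if r.known_copies is None else repr(r.known_copies),
            }
        )
    pd.DataFrame(rows, columns=list(TABLE_COLUMNS)).to_csv(path, index=False)


def assemble_experiment(
    layout: PlateLayout, setting_tables: Mapping[str, list[WellRecord]]
) -> PlateExperiment:
    """Combine per-setting Cq tables of the same physical plate.

    All settings must cover the identical (position, gene, task) set; a
    mismatch is reported listing the differing wells.
    """
    if not setting_tables:
        raise PlateError("need at least one setting table")
    keys = None
    ref_setting = None
    for sid, table in setting_tables.items():
        k = {(r.position, r.gene, r.task) for r in table}
        if keys is None:
            keys, ref_setting = k, sid
        elif k != keys:
            diff = sorted(p for p, _, _ in keys ^ k)
            raise PlateError(
                f"setting {sid!r} covers different wells than {ref_setting!r}: "
                + ", ".join(diff)
            )
    return PlateExperiment(layout=layout, settings=dict(setting_tables))
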