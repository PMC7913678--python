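"""Consolidation of per-oligonucleotide, per-condition biophysics datasets.

Raw traces enter through a templated XLSX workbook (one sheet per technique
plus an ``oligos`` metadata sheet and a ``buffers`` sheet), are validated and
grouped into :class:`DatabaseRecord` objects (one oligonucleotide x buffer
condition, with the attached CD / melting / NMR / MS / IMS datasets), and are
persisted as a versioned archive of tidy CSV tables with a JSON manifest —
a language-neutral on-disk format that round-trips numeric data exactly.

The 28-sequence study panel ships as a packaged CSV fixture
(:func:`load_reference_panel`); :func:`write_template_workbook` materializes
the workbook template, pre-filled with that panel, for users to paste their
instrument exports into.

Ratings (two-star / one-star / cross) encode expert judgment about whether a
sequence keeps its reference fold in the MS-compatible buffer; they are
stored verbatim and never computed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .cd import CDSpectrum
from .melting import MeltingCurve
from .ms import MassSpectrum
from .nmr import NMRTrace
from .seqcore import Oligonucleotide, Topology, SequenceError

__all__ = [
    "SCHEMA_VERSION",
    "BufferCondition",
    "DatabaseRecord",
    "Database",
    "PRESET_BUFFERS",
    "load_reference_panel",
    "write_template_workbook",
    "import_workbook",
    "filter_records",
    "save_db",
    "load_db",
    "summary_table",
    "render_report",
]

SCHEMA_VERSION = 1

TECHNIQUES = ("cd", "melting", "nmr", "ms", "ims")

#: Workbook sheet -> long-format column layout.
SHEET_COLUMNS = {
    "oligos": [
        "name", "sequence", "origin", "family", "pdb_ids", "strand_orientation",
        "quartets", "stacking", "loops", "grooves", "rating",
    ],
    "buffers": ["name", "components", "k_mM", "pH"],
    "cd": ["oligo", "buffer", "wavelength_nm", "signal_mdeg",
           "concentration_M", "pathlength_cm", "unit"],
    "melting": ["oligo", "buffer", "temperature_C", "absorbance",
                "wavelength_nm", "ramp", "concentration_M", "pathlength_cm",
                "unit"],
    "nmr": ["oligo", "buffer", "ppm", "intensity"],
    "ms": ["oligo", "buffer", "mz", "intensity"],
    "ims": ["oligo", "buffer", "arrival_time_ms", "mz", "intensity"],
}


@dataclass
class BufferCondition:
    """A named buffer: components, total K+ concentration and pH."""

    name: str
    components: list[tuple[str, float, str]] = field(default_factory=list)
    k_mM: float = 0.0
    pH: float = 7.0

    def __post_init__(self) -> None:
        for species, conc, _unit in self.components:
            if conc < 0:
                raise ValueError(f"negative concentration for {species!r}")
        if self.k_mM < 0:
            raise ValueError("K+ concentration must be >= 0")


#: The two study conditions, shipped as presets.
PRESET_BUFFERS = {
    "TMAA-1K": BufferCondition(
        "TMAA-1K",
        components=[("TMAA", 100.0, "mM"), ("KCl", 1.0, "mM")],
        k_mM=1.0,
        pH=7.0,
    ),
    "KPi-KCl": BufferCondition(
        "KPi-KCl",
        components=[("potassium phosphate", 25.0, "mM"), ("KCl", 75.0, "mM")],
        k_mM=100.0,
        pH=7.0,
    ),
}


@dataclass
class DatabaseRecord:
    """One oligonucleotide x buffer condition with its attached datasets."""

    oligo: str
    condition: str
    datasets: dict = field(default_factory=dict)  # technique -> object
    references: str = ""

    def techniques(self) -> list[str]:
        return sorted(self.datasets)


@dataclass
class Database:
    """Oligonucleotide registry, buffer registry and data records."""

    oligos: dict[str, Oligonucleotide] = field(default_factory=dict)
    buffers: dict[str, BufferCondition] = field(default_factory=dict)
    records: list[DatabaseRecord] = field(default_factory=list)
    import_errors: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.oligos)

    def add_oligo(self, oligo: Oligonucleotide) -> None:
        if oligo.name in self.oligos:
            raise ValueError(f"duplicate oligonucleotide name {oligo.name!r}")
        self.oligos[oligo.name] = oligo

    def record_for(self, oligo: str, condition: str) -> DatabaseRecord:
        for rec in self.records:
            if rec.oligo == oligo and rec.condition == condition:
                return rec
        rec = DatabaseRecord(oligo=oligo, condition=condition)
        self.records.append(rec)
        return rec


def _oligo_from_row(row: dict) -> Oligonucleotide:
    def get(key, default=""):
        v = row.get(key, default)
        return default if v is None or (isinstance(v, float) and np.isnan(v)) else v

    q = get("quartets", None)
    quartets = int(q) if q not in (None, "",) else None
    topo_fields = dict(
        strand_orientation=get("strand_orientation") or None,
        quartet_count=quartets,
        stacking_type=get("stacking") or None,
        loops=get("loops") or None,
        grooves=get("grooves") or None,
    )
    topology = Topology(**topo_fields) if any(
        v is not None for v in topo_fields.values()
    ) else None
    return Oligonucleotide(
        name=str(get("name")),
        sequence=str(get("sequence")),
        origin=str(get("origin")),
        family=get("family") or None,
        topology=topology,
        rating=get("rating") or None,
        pdb_ids=str(get("pdb_ids")),
        references=str(get("references")),
    )


def load_reference_panel() -> Database:
    """The packaged 28-sequence study panel (10 human-telomeric variants,
    parallel promoters/constructs, and other model folds) with topology
    annotations, melting temperatures and 5- charge-state K+ abundances."""
    with resources.as_file(resources.files("g4kit.data").joinpath("table1.csv")) as p:
        df = pd.read_csv(p)
    db = Database(buffers=dict(PRESET_BUFFERS))
    for _, row in df.iterrows():
        oligo = _oligo_from_row(row.to_dict())
        # panel annotations that are results, not inputs, ride along as
        # free-form metadata on the record
        db.add_oligo(oligo)
        rec = db.record_for(oligo.name, "TMAA-1K")
        rec.datasets["panel_annotations"] = {
            "tm_highK_C": row.get("tm_highK_C"),
            "tm_ms_buffer_C": row.get("tm_ms_buffer_C"),
            "k_species_pct": row.get("k_species_pct"),
            "cd_comparison": row.get("cd_comparison"),
            "nmr_comparison": row.get("nmr_comparison"),
            "topology_conclusion": row.get("topology_conclusion"),
        }
    return db


def write_template_workbook(path, db: Database | None = None) -> Path:
    """Write the templated XLSX workbook (sheet per technique + metadata).

    With ``db`` given, the ``oligos`` and ``buffers`` sheets are pre-filled
    from it and any attached long-format datasets are written to their
    technique sheets; otherwise the packaged reference panel is used.
    """
    from openpyxl import Workbook

    if db is None:
        db = load_reference_panel()
    wb = Workbook()
    wb.remove(wb.active)

    ws = wb.create_sheet("oligos")
    ws.append(SHEET_COLUMNS["oligos"])
    for oligo in db.oligos.values():
        topo = oligo.topology or Topology()
        ws.append([
            oligo.name, oligo.sequence, oligo.origin, oligo.family or "",
            oligo.pdb_ids, topo.strand_orientation or "",
            topo.quartet_count if topo.quartet_count is not None else "",
            topo.stacking_type or "", topo.loops or "", topo.grooves or "",
            oligo.rating or "",
        ])

    ws = wb.create_sheet("buffers")
    ws.append(SHEET_COLUMNS["buffers"])
    for buf in db.buffers.values():
        comps = "; ".join(f"{s} {c} {u}" for s, c, u in buf.components)
        ws.append([buf.name, comps, buf.k_mM, buf.pH])

    for technique in TECHNIQUES:
        ws = wb.create_sheet(technique)
        ws.append(SHEET_COLUMNS[technique])
        for rec in db.records:
            rows = _dataset_to_rows(technique, rec)
            for r in rows:
                ws.append(r)

    path = Path(path)
    wb.save(path)
    return path


def _dataset_to_rows(technique: str, rec: DatabaseRecord) -> list[list]:
    data = rec.datasets.get(technique)
    if data is None:
        return []
    o, b = rec.oligo, rec.condition
    if technique == "cd":
        return [
            [o, b, wl, s, data.concentration_M, data.pathlength_cm, data.unit]
            for wl, s in zip(data.wavelength_nm, data.signal)
        ]
    if technique == "melting":
        return [
            [o, b, t, a, data.wavelength_nm, data.ramp, data.concentration_M,
             data.pathlength_cm, data.unit]
            for t, a in zip(data.temperature_C, data.absorbance)
        ]
    if technique == "nmr":
        return [[o, b, p, i] for p, i in zip(data.ppm, data.intensity)]
    if technique == "ms":
        return [[o, b, m, i] for m, i in zip(data.mz, data.intensity)]
    if technique == "ims":
        return [[o, b, t, m, i] for t, m, i in np.asarray(data)]
    return []


def import_workbook(path) -> Database:
    """Import a templated workbook into a validated :class:`Database`.

    A missing ``oligos`` metadata sheet is an error.  Malformed oligo rows
    are rejected individually and reported in ``Database.import_errors``;
    technique rows referencing an unknown oligo name raise an error listing
    the valid names.
    """
    from openpyxl import load_workbook

    wb = load_workbook(path, read_only=True, data_only=True)
    if "oligos" not in wb.sheetnames:
        raise ValueError("workbook has no 'oligos' metadata sheet")

    db = Database()

    def sheet_rows(name: str):
        ws = wb[name]
        rows = ws.iter_rows(values_only=True)
        try:
            header = [str(h).strip() if h is not None else "" for h in next(rows)]
        except StopIteration:
            return
        for values in rows:
            if all(v is None for v in values):
                continue
            yield dict(zip(header, values))

    for i, row in enumerate(sheet_rows("oligos"), start=2):
        try:
            db.add_oligo(_oligo_from_row(row))
        except (SequenceError, ValueError) as exc:
            db.import_errors.append(f"oligos row {i} ({row.get('name')!r}): {exc}")

    if "buffers" in wb.sheetnames:
        for row in sheet_rows("buffers"):
            comps = []
            for part in str(row.get("components") or "").split(";"):
                tokens = part.strip().rsplit(" ", 2)
                if len(tokens) == 3:
                    comps.append((tokens[0], float(tokens[1]), tokens[2]))
            db.buffers[str(row["name"])] = BufferCondition(
                name=str(row["name"]),
                components=comps,
                k_mM=float(row.get("k_mM") or 0.0),
                pH=float(row.get("pH") or 7.0),
            )

    for technique in TECHNIQUES:
        if technique not in wb.sheetnames:
            continue
        groups: dict[tuple[str, str], list[dict]] = {}
        for row in sheet_rows(technique):
            oligo = str(row.get("oligo"))
            if oligo not in db.oligos:
                raise ValueError(
                    f"{technique} sheet references unknown oligo {oligo!r}; "
                    f"valid names: {sorted(db.oligos)}"
                )
            groups.setdefault((oligo, str(row.get("buffer"))), []).append(row)
        for (oligo, buffer), rows in groups.items():
            rec = db.record_for(oligo, buffer)
            rec.datasets[technique] = _rows_to_dataset(technique, rows, buffer)

    if not db.oligos and not db.import_errors:
        import warnings

        warnings.warn("workbook contained no oligonucleotide entries", stacklevel=2)
    wb.close()
    return db


def _str_or(value, default: str) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return default
    return str(value)


def _opt_float(value) -> float | None:
    if value is None or value == "":
        return None
    value = float(value)
    return None if np.isnan(value) else value


def _rows_to_dataset(technique: str, rows: list[dict], buffer: str):
    def col(name):
        return np.array([float(r[name]) for r in rows])

    if technique == "cd":
        return CDSpectrum(
            col("wavelength_nm"),
            col("signal_mdeg"),
            concentration_M=_opt_float(rows[0].get("concentration_M")),
            pathlength_cm=_opt_float(rows[0].get("pathlength_cm")),
            buffer=buffer,
            unit=_str_or(rows[0].get("unit"), "mdeg"),
        )
    if technique == "melting":
        return MeltingCurve(
            col("temperature_C"),
            col("absorbance"),
            wavelength_nm=float(rows[0].get("wavelength_nm") or 295),
            ramp=_str_or(rows[0].get("ramp"), "heating"),
            buffer=buffer,
            concentration_M=_opt_float(rows[0].get("concentration_M")),
            pathlength_cm=_opt_float(rows[0].get("pathlength_cm")),
            unit=_str_or(rows[0].get("unit"), "absorbance"),
        )
    if technique == "nmr":
        return NMRTrace(col("ppm"), col("intensity"))
    if technique == "ms":
        mz, inten = col("mz"), col("intensity")
        order = np.argsort(mz)
        return MassSpectrum(mz[order], inten[order])
    if technique == "ims":
        return np.column_stack([col("arrival_time_ms"), col("mz"), col("intensity")])
    raise ValueError(f"unknown technique {technique!r}")


def filter_records(db: Database, **predicates) -> Database:
    """Project a sub-database matching all given predicates.

    Supported keys: ``name``, ``sequence`` (substring), ``family``,
    ``topology`` (strand-orientation substring, case-insensitive),
    ``buffer`` (condition name), ``cation`` (minimum K+ concentration in mM
    via ``cation=("K", min_mM)`` or any-K via ``cation="K"``), ``rating``.
    The input database is untouched.
    """
    allowed = {"name", "sequence", "family", "topology", "buffer", "cation", "rating"}
    unknown = set(predicates) - allowed
    if unknown:
        raise ValueError(f"unknown filter field(s): {sorted(unknown)}")

    def keep_oligo(o: Oligonucleotide) -> bool:
        if "name" in predicates and o.name != predicates["name"]:
            return False
        if "sequence" in predicates and predicates["sequence"] not in o.sequence:
            return False
        if "family" in predicates and o.family != predicates["family"]:
            return False
        if "rating" in predicates and o.rating != predicates["rating"]:
            return False
        if "topology" in predicates:
            want = str(predicates["topology"]).lower()
            have = (o.topology.strand_orientation or "") if o.topology else ""
            if want not in have.lower():
                return False
        return True

    def keep_buffer(name: str) -> bool:
        if "buffer" in predicates and name != predicates["buffer"]:
            return False
        if "cation" in predicates:
            buf = db.buffers.get(name)
            spec = predicates["cation"]
            min_mM = 0.0
            if isinstance(spec, (tuple, list)):
                cat, min_mM = spec[0], float(spec[1])
            else:
                cat = spec
            if cat.upper() != "K":
                return False  # only K+ is tracked quantitatively
            if buf is None or not buf.k_mM > min_mM:
                return False
        return True

    oligos = {n: o for n, o in db.oligos.items() if keep_oligo(o)}
    records = [
        rec
        for rec in db.records
        if rec.oligo in oligos and keep_buffer(rec.condition)
    ]
    buffers = {n: b for n, b in db.buffers.items() if keep_buffer(n)}
    return Database(oligos=oligos, buffers=buffers, records=records)


# ---------------------------------------------------------------------------
# on-disk archive

_FLOAT_FMT = "%.17g"  # round-trips IEEE doubles exactly


def save_db(db: Database, path) -> Path:
    """Serialize to a versioned directory of tidy CSV tables + manifest."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)

    oligo_rows = []
    for o in db.oligos.values():
        topo = o.topology or Topology()
        oligo_rows.append(
            {
                "name": o.name, "sequence": o.sequence, "origin": o.origin,
                "family": o.family, "pdb_ids": o.pdb_ids,
                "references": o.references,
                "strand_orientation": topo.strand_orientation,
                "quartets": topo.quartet_count, "stacking": topo.stacking_type,
                "loops": topo.loops, "grooves": topo.grooves, "rating": o.rating,
            }
        )
    pd.DataFrame(
        oligo_rows,
        columns=["name", "sequence", "origin", "family", "pdb_ids",
                 "references", "strand_orientation", "quartets", "stacking",
                 "loops", "grooves", "rating"],
    ).to_csv(root / "oligos.csv", index=False)

    buffer_rows = [
        {
            "name": b.name,
            "components": "; ".join(f"{s} {c} {u}" for s, c, u in b.components),
            "k_mM": b.k_mM,
            "pH": b.pH,
        }
        for b in db.buffers.values()
    ]
    pd.DataFrame(
        buffer_rows, columns=["name", "components", "k_mM", "pH"]
    ).to_csv(root / "buffers.csv", index=False)

    tables = ["oligos", "buffers"]
    annotations = {}
    for technique in TECHNIQUES:
        rows = []
        for rec in db.records:
            for r in _dataset_to_rows(technique, rec):
                rows.append([rec.oligo, rec.condition] + list(r[2:]))
        if rows:
            cols = ["oligo", "buffer"] + SHEET_COLUMNS[technique][2:]
            df = pd.DataFrame(rows, columns=cols)
            df.to_csv(root / f"{technique}.csv", index=False,
                      float_format=_FLOAT_FMT)
            tables.append(technique)
    for rec in db.records:
        if "panel_annotations" in rec.datasets:
            annotations[f"{rec.oligo}\t{rec.condition}"] = {
                k: (None if isinstance(v, float) and np.isnan(v) else v)
                for k, v in rec.datasets["panel_annotations"].items()
            }

    record_rows = [
        {"oligo": rec.oligo, "condition": rec.condition,
         "techniques": ";".join(rec.techniques()), "references": rec.references}
        for rec in db.records
    ]
    pd.DataFrame(
        record_rows, columns=["oligo", "condition", "techniques", "references"]
    ).to_csv(root / "records.csv", index=False)
    tables.append("records")

    manifest = {
        "format": "g4kit-database",
        "schema_version": SCHEMA_VERSION,
        "tables": tables,
        "panel_annotations": annotations,
    }
    (root / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return root


def load_db(path) -> Database:
    """Load a database archive written by :func:`save_db`.

    Archives with a different schema version are refused explicitly.
    """
    root = Path(path)
    manifest_path = root / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json under {root}")
    manifest = json.loads(manifest_path.read_text())
    version = manifest.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(
            f"archive schema version {version!r} is not supported by this "
            f"build (expected {SCHEMA_VERSION}); re-export the database or "
            "use a matching g4kit release"
        )

    db = Database()
    odf = pd.read_csv(root / "oligos.csv")
    for _, row in odf.iterrows():
        db.add_oligo(_oligo_from_row(row.to_dict()))
    bdf = pd.read_csv(root / "buffers.csv")
    for _, row in bdf.iterrows():
        comps = []
        for part in str(row.get("components") or "").split(";"):
            tokens = part.strip().rsplit(" ", 2)
            if len(tokens) == 3:
                comps.append((tokens[0], float(tokens[1]), tokens[2]))
        db.buffers[str(row["name"])] = BufferCondition(
            str(row["name"]), comps, float(row.get("k_mM") or 0.0),
            float(row.get("pH") or 7.0),
        )

    rdf = pd.read_csv(root / "records.csv") if (root / "records.csv").exists() else None
    if rdf is not None:
        for _, row in rdf.iterrows():
            rec = db.record_for(str(row["oligo"]), str(row["condition"]))
            rec.references = str(row.get("references") or "")

    for technique in TECHNIQUES:
        f = root / f"{technique}.csv"
        if not f.exists():
            continue
        df = pd.read_csv(f, float_precision="round_trip")
        for (oligo, buffer), grp in df.groupby(["oligo", "buffer"], sort=False):
            rec = db.record_for(str(oligo), str(buffer))
            rows = grp.to_dict("records")
            rec.datasets[technique] = _rows_to_dataset(technique, rows, str(buffer))

    for key, ann in manifest.get("panel_annotations", {}).items():
        oligo, condition = key.split("\t")
        db.record_for(oligo, condition).datasets["panel_annotations"] = ann
    return db


# ---------------------------------------------------------------------------
# summaries and reports


def summary_table(db: Database, charge: int = 5) -> pd.DataFrame:
    """One row per oligo x condition: Tm, theta(25 C), per-z MS abundances,
    CD stacking class and rating.  Missing techniques yield empty cells."""
    from . import cd as cdmod
    from . import melting as meltmod
    from . import ms as msmod

    rows = []
    for rec in db.records:
        oligo = db.oligos.get(rec.oligo)
        row: dict = {
            "oligo": rec.oligo,
            "condition": rec.condition,
            "sequence": oligo.sequence if oligo else "",
            "rating": oligo.rating if oligo else None,
            "Tm_C": np.nan,
            "theta_25C": np.nan,
            "cd_class": "",
        }
        curve = rec.datasets.get("melting")
        if curve is not None:
            fit = meltmod.fit_two_state(curve)
            if fit.converged and fit.baselines_ok:
                row["Tm_C"] = fit.Tm_C
                row["theta_25C"] = meltmod.theta_at_25(fit)
        spec = rec.datasets.get("cd")
        if spec is not None and oligo is not None:
            if spec.unit == "mdeg" and spec.concentration_M and spec.pathlength_cm:
                spec = cdmod.mdeg_to_delta_epsilon(spec)
            if spec.unit == "delta_epsilon":
                try:
                    row["cd_class"] = cdmod.classify_stacking(spec)
                except ValueError:
                    row["cd_class"] = ""
        ms_spec = rec.datasets.get("ms")
        if ms_spec is not None and oligo is not None:
            assigns = msmod.annotate(ms_spec, oligo.sequence, charges=(charge,))
            for s in assigns:
                row[f"pct_{s.b}K_z{s.z}"] = s.relative_abundance
        rows.append(row)
    return pd.DataFrame(rows)


def render_report(db: Database, oligo: str, fmt: str = "html",
                  out_dir: str | Path = "reports") -> Path:
    """Render the per-oligonucleotide report (all technique panels).

    ``fmt`` is ``"html"`` (canonical) or ``"md"``.  Panels for techniques
    with no data show an explicit "not available" placeholder; nothing is
    fabricated.  Returns the written file path (``reports/<oligo>.<fmt>``).
    """
    from .report import build_report

    if oligo not in db.oligos:
        raise KeyError(
            f"oligo {oligo!r} not in database; known: {sorted(db.oligos)}"
        )
    if fmt not in ("html", "md"):
        raise ValueError("format must be 'html' or 'md'")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    content = build_report(db, oligo, fmt)
    path = out_dir / f"{oligo}.{fmt}"
    path.write_text(content)
    return path
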