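"""Data model, I/O, validation and per-arm summaries for PDX trial measurements.

A trial is a long-format table of repeated tumor-volume (and optionally body
weight) measurements: one row per animal per day.  The canonical columns are

    tumor_id, tumor_type, arm, animal_id, day, volume, body_weight

with volume in mm**3, body weight in g and day counted from treatment start
(T0).  :class:`TrialDataset` wraps such a table together with the identity of
the vehicle/control arm and is the input to every analysis in this package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_COLUMNS",
    "DIALECTS",
    "CONTROL_ALIASES",
    "TrialDataset",
    "PatternCode",
    "ValidationReport",
    "read_trial",
    "write_trial",
    "validate",
    "infer_pattern",
    "relative_change",
    "summarize_arm",
]

CANONICAL_COLUMNS = (
    "tumor_id",
    "tumor_type",
    "arm",
    "animal_id",
    "day",
    "volume",
    "body_weight",
)

REQUIRED_COLUMNS = ("tumor_id", "arm", "animal_id", "day", "volume")

#: Named column-mapping presets (canonical field -> source column).
DIALECTS: dict[str, dict[str, str]] = {
    "canonical": {c: c for c in CANONICAL_COLUMNS},
    # Novartis PDX-encyclopedia export dialect.  No animal id column exists:
    # each model contributes a single animal per arm, so the model id doubles
    # as the animal id.
    "nibr-pdxe": {
        "tumor_id": "Model",
        "tumor_type": "Tumor Type",
        "arm": "Treatment",
        "day": "Days Post T0",
        "volume": "Volume",
    },
}

#: Case-insensitive arm names recognised as the vehicle arm when no explicit
#: control is given.
CONTROL_ALIASES = ("vehicle", "control", "untreated")


class TrialDataError(ValueError):
    """Fatal problem with trial input data."""


@dataclass
class ValidationReport:
    """Outcome of :func:`validate`: per-record issues plus dataset counts."""

    errors: list[tuple[str, str, str]] = field(default_factory=list)
    n_animals: int = 0
    n_tumors: int = 0
    n_arms: int = 0
    n_timepoints: int = 0

    @property
    def fatal(self) -> list[tuple[str, str, str]]:
        return [e for e in self.errors if e[0] == "fatal"]

    @property
    def warnings(self) -> list[tuple[str, str, str]]:
        return [e for e in self.errors if e[0] == "warning"]

    @property
    def ok(self) -> bool:
        return not self.fatal


@dataclass
class PatternCode:
    """Trial-design pattern.

    The code encodes (number of tumors, number of treatment arms, animals per
    tumor-by-arm cell), with ``1`` meaning single and a letter meaning
    multiple: ``1AN`` (one tumor, several arms, several animals), ``T1N``
    (several tumors, one treatment arm vs vehicle), ``TA1`` (several tumors
    and arms, one animal per cell — the mouse-clinical-trial design) and
    ``TAN`` (several of everything).
    """

    code: str
    n_tumors: int
    n_arms_per_tumor: int
    n_animals_per_cell: int
    degenerate: bool = False
    note: str = ""


@dataclass
class TrialDataset:
    """Validated long-format repeated-measures trial table."""

    records: pd.DataFrame
    control_arm: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise TrialDataError(f"missing required columns: {missing}")
        for c in CANONICAL_COLUMNS:
            if c not in df.columns:
                df[c] = np.nan if c in ("body_weight", "volume", "day") else pd.NA
        df = df[list(CANONICAL_COLUMNS)].copy()
        for c in ("tumor_id", "arm", "animal_id"):
            df[c] = df[c].astype(str)
        for c in ("day", "volume", "body_weight"):
            df[c] = pd.to_numeric(df[c], errors="raise")
        df = df.sort_values(["tumor_id", "arm", "animal_id", "day"], kind="stable")
        self.records = df.reset_index(drop=True)
        if self.control_arm is not None and len(df):
            if self.control_arm not in set(df["arm"]):
                raise TrialDataError(
                    f"control arm {self.control_arm!r} not present in data"
                )
        dup = df.duplicated(subset=["tumor_id", "arm", "animal_id", "day"])
        if dup.any():
            row = df[dup].iloc[0]
            raise TrialDataError(
                "duplicate measurement for "
                f"(tumor={row.tumor_id}, arm={row.arm}, "
                f"animal={row.animal_id}, day={row.day})"
            )

    # -- convenience accessors -------------------------------------------------
    @property
    def arms(self) -> list[str]:
        return sorted(self.records["arm"].unique())

    @property
    def tumors(self) -> list[str]:
        return sorted(self.records["tumor_id"].unique())

    def subset(self, tumor_id: str | None = None, arms: list[str] | None = None) -> "TrialDataset":
        df = self.records
        if tumor_id is not None:
            df = df[df["tumor_id"] == tumor_id]
        if arms is not None:
            df = df[df["arm"].isin(arms)]
        ctrl = self.control_arm if self.control_arm in set(df["arm"]) else None
        return TrialDataset(df.copy(), control_arm=ctrl, meta=dict(self.meta))

    def resolve_control(self, required: bool = True) -> str | None:
        """Explicit control flag wins; else match arm names against the usual
        vehicle aliases; else fatal when a control is required."""
        if self.control_arm is not None:
            return self.control_arm
        for arm in self.arms:
            if arm.strip().lower() in CONTROL_ALIASES:
                return arm
        if required:
            raise TrialDataError(
                "no control arm: pass control_arm explicitly or name an arm "
                f"one of {CONTROL_ALIASES}"
            )
        return None

    def animals(self) -> pd.DataFrame:
        """One row per animal: (tumor_id, arm, animal_id)."""
        return (
            self.records[["tumor_id", "arm", "animal_id"]]
            .drop_duplicates()
            .reset_index(drop=True)
        )


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    return pd.read_csv(path, sep=sep)


def read_trial(
    path: str | Path,
    column_map: dict[str, str] | str = "canonical",
    control_arm: str | None = None,
) -> TrialDataset:
    """Read a delimited trial table.

    Parameters
    ----------
    path:
        CSV or TSV file with a header row (TSV inferred from the ``.tsv`` /
        ``.txt`` suffix).
    column_map:
        Either a dialect preset name (``"canonical"``, ``"nibr-pdxe"``) or an
        explicit mapping of canonical field name to source column name.
    control_arm:
        Label of the vehicle arm, if known.
    """
    if isinstance(column_map, str):
        try:
            column_map = DIALECTS[column_map]
        except KeyError:
            raise TrialDataError(
                f"unknown dialect {column_map!r}; available: {sorted(DIALECTS)}"
            ) from None
    raw = _read_table(path)
    # optional fields simply stay absent when their column is missing
    column_map = {
        canon: src
        for canon, src in column_map.items()
        if canon in REQUIRED_COLUMNS or src in raw.columns
    }
    missing = [src for src in column_map.values() if src not in raw.columns]
    if missing:
        raise TrialDataError(f"mapped column(s) not in file: {missing}")
    df = pd.DataFrame({canon: raw[src] for canon, src in column_map.items()})
    if "animal_id" not in df.columns:
        # single-animal-per-arm dialects (e.g. NIBR): model id identifies the animal
        df["animal_id"] = df["tumor_id"].astype(str)
    for c in ("day", "volume"):
        try:
            df[c] = pd.to_numeric(df[c], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(df[c], errors="coerce").isna() & df[c].notna()
            rows = list(df.index[bad][:5])
            raise TrialDataError(f"non-numeric {c} at rows {rows}") from exc
    ds = TrialDataset(
        df,
        control_arm=control_arm,
        meta={"source": str(path), "column_map": dict(column_map)},
    )
    return ds


def write_trial(ds: TrialDataset, path: str | Path) -> None:
    """Write the canonical long-format table (CSV, or TSV by suffix)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    out = ds.records.copy()
    # drop all-empty optional columns rather than writing fabricated blanks
    for c in ("tumor_type", "body_weight"):
        if out[c].isna().all():
            out = out.drop(columns=c)
    out.to_csv(path, sep=sep, index=False)


def validate(ds: TrialDataset) -> ValidationReport:
    """Check a dataset for problems that block or degrade analysis.

    Fatal issues (negative volumes, negative days) block downstream analysis;
    warnings (missing baseline, < 2 timepoints, single-animal arms) restrict
    which analyses are meaningful.
    """
    df = ds.records
    rep = ValidationReport()
    rep.n_animals = len(ds.animals())
    rep.n_tumors = df["tumor_id"].nunique()
    rep.n_arms = df["arm"].nunique()
    rep.n_timepoints = df["day"].nunique()
    if df.empty:
        rep.errors.append(("warning", "<dataset>", "no records"))
        return rep

    neg = df[df["volume"] < 0]
    for _, row in neg.iterrows():
        rep.errors.append(
            ("fatal", _locator(row), f"negative volume {row.volume}")
        )
    negday = df[df["day"] < 0]
    for _, row in negday.iterrows():
        rep.errors.append(("fatal", _locator(row), f"negative day {row.day}"))
    bw = df[df["body_weight"].notna() & (df["body_weight"] <= 0)]
    for _, row in bw.iterrows():
        rep.errors.append(
            ("fatal", _locator(row), f"non-positive body weight {row.body_weight}")
        )

    for (tumor, arm, animal), g in df.groupby(["tumor_id", "arm", "animal_id"]):
        loc = f"tumor={tumor}/arm={arm}/animal={animal}"
        if g["day"].min() != 0:
            rep.errors.append(("warning", loc, "missing baseline (no day 0)"))
        if len(g) < 2:
            rep.errors.append(
                ("warning", loc, "fewer than 2 timepoints: cannot compute growth")
            )

    for (tumor, arm), g in df.groupby(["tumor_id", "arm"]):
        if g["animal_id"].nunique() == 1 and rep.n_animals > 1:
            rep.errors.append(
                (
                    "warning",
                    f"tumor={tumor}/arm={arm}",
                    "single animal: no within-arm variance",
                )
            )
    return rep


def _locator(row: pd.Series) -> str:
    return (
        f"tumor={row.tumor_id}/arm={row.arm}/animal={row.animal_id}/day={row.day}"
    )


def infer_pattern(ds: TrialDataset) -> PatternCode:
    """Classify the trial design into 1AN / T1N / TA1 / TAN.

    The code is a deterministic function of three counts: the number of
    tumors, the number of non-control arms (max over tumors) and the median
    number of animals per tumor-by-arm cell.  Degenerate designs (single
    tumor *and* single arm, ...) map to the nearest code with
    ``degenerate=True``.
    """
    df = ds.records
    if df.empty:
        raise TrialDataError("cannot infer pattern of an empty dataset")
    control = ds.resolve_control(required=False)
    n_tumors = df["tumor_id"].nunique()
    noncontrol = df[df["arm"] != control] if control is not None else df
    n_arms = int(
        noncontrol.groupby("tumor_id")["arm"].nunique().max()
    )
    cells = df.groupby(["tumor_id", "arm"])["animal_id"].nunique()
    n_per_cell = int(math.floor(cells.median()))

    degenerate = False
    note = ""
    if n_tumors == 1:
        code = "1AN"
        if n_arms <= 1 or n_per_cell <= 1:
            degenerate = True
            note = "single tumor with a single arm or single animals per arm"
    elif n_per_cell <= 1:
        code = "TA1"
        if n_arms <= 1:
            degenerate = True
            note = "multiple tumors but a single treatment arm with single animals"
    elif n_arms == 1:
        code = "T1N"
    else:
        code = "TAN"
    return PatternCode(
        code=code,
        n_tumors=n_tumors,
        n_arms_per_tumor=n_arms,
        n_animals_per_cell=n_per_cell,
        degenerate=degenerate,
        note=note,
    )


def relative_change(ds: TrialDataset, quantity: str = "volume") -> pd.DataFrame:
    """Percent change from each animal's own baseline.

    ``pct_change(day) = 100 * (x_day - x_0) / x_0`` with the baseline taken at
    day 0.  Animals without a positive day-0 value are excluded (they have no
    usable baseline); the returned frame carries them in ``attrs["excluded"]``.
    """
    if quantity not in ("volume", "body_weight"):
        raise TrialDataError(f"unknown quantity {quantity!r}")
    df = ds.records[ds.records[quantity].notna()]
    rows = []
    excluded = []
    for (tumor, arm, animal), g in df.groupby(["tumor_id", "arm", "animal_id"]):
        g = g.sort_values("day")
        base = g[g["day"] == 0]
        if base.empty or base[quantity].iloc[0] <= 0:
            excluded.append((tumor, arm, animal))
            continue
        x0 = base[quantity].iloc[0]
        for _, r in g.iterrows():
            rows.append(
                (tumor, arm, animal, r["day"], 100.0 * (r[quantity] - x0) / x0)
            )
    out = pd.DataFrame(
        rows, columns=["tumor_id", "arm", "animal_id", "day", "pct_change"]
    )
    out.attrs["quantity"] = quantity
    out.attrs["excluded"] = excluded
    return out


def summarize_arm(ds: TrialDataset, center: str = "mean") -> pd.DataFrame:
    """Per-arm, per-day volume summary: n, center (mean or median) and SEM.

    SEM is the sample standard deviation over animals divided by sqrt(n) and
    is reported as NaN when n < 2.
    """
    if center not in ("mean", "median"):
        raise TrialDataError(f"center must be 'mean' or 'median', got {center!r}")
    df = ds.records
    grouped = df.groupby(["tumor_id", "arm", "day"])["volume"]
    out = grouped.agg(
        n="count",
        center=center,
        sd=lambda v: v.std(ddof=1),
    ).reset_index()
    out["sem"] = out["sd"] / np.sqrt(out["n"])
    out.loc[out["n"] < 2, "sem"] = np.nan
    out = out.drop(columns="sd")
    out.attrs["center"] = center
    return out
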