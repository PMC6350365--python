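"""Tumor growth inhibition (TGI) rate.

TGI quantifies a treatment arm against the vehicle arm at each timepoint:

    TGI(t) = (1 - F(V_T) / F(V_C)) * 100%

where F maps an arm's center (mean or median) volume curve to a scalar.
Three F functions are provided:

- ``diff``:  F = V_t - V_0 (volume gained since baseline),
- ``ratio``: F = V_t / V_0 (fold change from baseline),
- ``auc``:   F = trapezoidal area under the center curve from day 0 to t.

With ``diff``, a treatment that exactly holds the tumor at baseline while the
control grows scores 100%; regression below baseline scores above 100%.  When
the control arm itself fails to grow (F_C <= 0 under diff/auc) the ratio in
the definition is uninterpretable and the row is reported as undefined rather
than as a sign-flipped number.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trial_data import TrialDataset, TrialDataError

__all__ = ["TGISeries", "arm_center_series", "auc_trapezoid", "compute_tgi"]

F_KINDS = ("diff", "ratio", "auc")


@dataclass
class TGISeries:
    """Per-day TGI of one treatment arm vs the control, under one F function."""

    tumor_id: str
    arm: str
    control_arm: str
    f_kind: str
    center: str
    rows: pd.DataFrame  # day, tgi_percent, defined, note

    def at_end(self) -> float | None:
        """TGI at the last defined day, if any."""
        ok = self.rows[self.rows["defined"]]
        return None if ok.empty else float(ok["tgi_percent"].iloc[-1])


def arm_center_series(
    ds: TrialDataset, tumor_id: str, arm: str, center: str = "mean"
) -> tuple[np.ndarray, np.ndarray]:
    """Per-day center (mean or median) volume of one arm of one tumor."""
    if center not in ("mean", "median"):
        raise TrialDataError(f"center must be 'mean' or 'median', got {center!r}")
    df = ds.records
    sel = df[(df["tumor_id"] == tumor_id) & (df["arm"] == arm)]
    if sel.empty:
        raise TrialDataError(f"no data for tumor {tumor_id!r}, arm {arm!r}")
    agg = sel.groupby("day")["volume"].agg(center).sort_index()
    return agg.index.to_numpy(float), agg.to_numpy(float)


def auc_trapezoid(days: np.ndarray, volumes: np.ndarray) -> float:
    """Trapezoidal area under a volume curve (mm^3 * day)."""
    days = np.asarray(days, dtype=float)
    volumes = np.asarray(volumes, dtype=float)
    if days.size < 2:
        raise TrialDataError("AUC needs at least 2 points")
    if np.any(np.diff(days) <= 0):
        raise TrialDataError("days must be strictly increasing")
    return float(np.trapezoid(volumes, days))


def _f_values(days: np.ndarray, vols: np.ndarray, f_kind: str) -> dict[float, float]:
    """F evaluated at each day > 0 (plus day 0 for ratio, where F = 1)."""
    v0 = vols[0]
    out: dict[float, float] = {}
    for i, t in enumerate(days):
        if f_kind == "diff":
            if t > 0:
                out[t] = vols[i] - v0
        elif f_kind == "ratio":
            out[t] = vols[i] / v0 if v0 > 0 else np.nan
        else:  # auc from day 0 to t
            if t > 0:
                out[t] = auc_trapezoid(days[: i + 1], vols[: i + 1])
    return out


def compute_tgi(
    ds: TrialDataset,
    tumor_id: str | None = None,
    control_arm: str | None = None,
    f_kind: str = "diff",
    center: str = "mean",
    at: str = "all_days",
) -> list[TGISeries]:
    """TGI of every treatment arm against the control, per tumor.

    Both arms' center curves are evaluated on the days they share (the
    baseline day 0 must be among them).  ``at="end"`` keeps only the last
    shared day.  Rows where the control F is non-positive (diff/auc) or
    undefined are flagged ``defined=False`` with the note "control not
    growing".
    """
    if f_kind not in F_KINDS:
        raise TrialDataError(f"f_kind must be one of {F_KINDS}, got {f_kind!r}")
    if at not in ("all_days", "end"):
        raise TrialDataError(f"at must be 'all_days' or 'end', got {at!r}")
    control = control_arm or ds.resolve_control()
    tumors = [tumor_id] if tumor_id is not None else ds.tumors
    out: list[TGISeries] = []
    for tumor in tumors:
        tdf = ds.records[ds.records["tumor_id"] == tumor]
        arms = sorted(tdf["arm"].unique())
        if control not in arms:
            raise TrialDataError(f"control arm {control!r} missing for tumor {tumor!r}")
        c_days, c_vols = arm_center_series(ds, tumor, control, center)
        if 0 not in c_days:
            raise TrialDataError(f"control arm of tumor {tumor!r} has no baseline day 0")
        for arm in arms:
            if arm == control:
                continue
            t_days, t_vols = arm_center_series(ds, tumor, arm, center)
            common = np.intersect1d(c_days, t_days)
            if 0 not in common:
                raise TrialDataError(
                    f"arm {arm!r} of tumor {tumor!r} shares no baseline with control"
                )
            if common[common > 0].size == 0:
                raise TrialDataError(
                    f"arm {arm!r} and control share no post-baseline day"
                )
            ci = np.isin(c_days, common)
            ti = np.isin(t_days, common)
            f_c = _f_values(c_days[ci], c_vols[ci], f_kind)
            f_t = _f_values(t_days[ti], t_vols[ti], f_kind)
            rows = []
            for day in sorted(f_t):
                fc, ft = f_c[day], f_t[day]
                if np.isnan(fc) or np.isnan(ft) or (fc <= 0 and day > 0):
                    rows.append((day, np.nan, False, "control not growing"))
                else:
                    rows.append((day, (1.0 - ft / fc) * 100.0, True, ""))
            table = pd.DataFrame(rows, columns=["day", "tgi_percent", "defined", "note"])
            if at == "end":
                table = table.tail(1).reset_index(drop=True)
            out.append(
                TGISeries(
                    tumor_id=tumor,
                    arm=arm,
                    control_arm=control,
                    f_kind=f_kind,
                    center=center,
                    rows=table,
                )
            )
    return out


def tgi_table(series: list[TGISeries]) -> pd.DataFrame:
    """Flatten TGISeries objects into one long-format table."""
    frames = []
    for s in series:
        t = s.rows.copy()
        t.insert(0, "tumor_id", s.tumor_id)
        t.insert(1, "arm", s.arm)
        t.insert(2, "f_kind", s.f_kind)
        frames.append(t)
    if not frames:
        return pd.DataFrame(
            columns=["tumor_id", "arm", "f_kind", "day", "tgi_percent", "defined", "note"]
        )
    return pd.concat(frames, ignore_index=True)
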