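"""Animal-level drug-response labeling and arm-level response indices.

Each animal's trajectory is condensed to a response level — complete response
(CR), partial response (PR), stable disease (SD) or progressive disease
(PD) — under one of three published standards:

- ``npdxe``: the PDX-encyclopedia criteria based on BestResponse (minimum
  percent volume change from baseline over days at or past an eligibility
  day, default day 10) and BestAvgResponse (minimum running mean of the
  percent change);
- ``pptp``:  the pediatric-testing-program criteria on relative tumor volume
  RTV(t) = V_t / V_0 plus a measurability cutoff in absolute mm^3;
- ``rc``:    volume-adapted RECIST cutoffs on the percent change at the last
  measurement day.

Arm-level indices are the response rate RR = (nCR + nPR)/n and the disease
control rate DCR = (nCR + nPR + nSD)/n.  All numeric cutoffs are fields of
:class:`Thresholds` and can be adjusted to the mouse strain and growth
kinetics at hand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trial_data import TrialDataset, TrialDataError

__all__ = [
    "AnimalTrajectory",
    "ResponseCall",
    "Thresholds",
    "ArmResponseSummary",
    "trajectories",
    "delta_volume_pct",
    "best_response",
    "best_avg_response",
    "label_npdxe",
    "label_pptp",
    "label_rc",
    "label_animal",
    "label_dataset",
    "arm_indices",
    "rank_arms",
]

LEVELS = ("CR", "PR", "SD", "PD")
STANDARDS = ("npdxe", "pptp", "rc")


@dataclass(frozen=True)
class AnimalTrajectory:
    """One animal's time-ordered volume series, day 0 (baseline) first."""

    tumor_id: str
    arm: str
    animal_id: str
    days: tuple[float, ...]
    volumes: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.days) != len(self.volumes):
            raise TrialDataError("days and volumes must align")
        if len(self.days) == 0:
            raise TrialDataError("empty trajectory")
        if any(b <= a for a, b in zip(self.days, self.days[1:])):
            raise TrialDataError("days must be strictly increasing")
        if self.days[0] != 0:
            raise TrialDataError("trajectory must start at day 0")
        if self.volumes[0] <= 0:
            raise TrialDataError("baseline volume must be positive")
        if any(v < 0 for v in self.volumes):
            raise TrialDataError("volumes must be non-negative")


@dataclass(frozen=True)
class Thresholds:
    """User-adjustable cutoffs of the three labeling standards.

    NPDXE cutoffs apply to (BestResponse, BestAvgResponse) in percent; a
    level is called when BestResponse is below the first member AND
    BestAvgResponse below the second, testing CR, PR, SD in that order.
    PPTP works on relative tumor volume; RC on the final percent change.
    """

    # npdxe: (best_response, best_avg_response) upper bounds, percent
    npdxe_cr: tuple[float, float] = (-95.0, -40.0)
    npdxe_pr: tuple[float, float] = (-50.0, -20.0)
    npdxe_sd: tuple[float, float] = (35.0, 30.0)
    npdxe_min_day: float = 10.0
    # pptp
    pptp_measurable_mm3: float = 100.0   # any volume below this is a CR
    pptp_pr_rtv: float = 0.5             # min RTV at or below -> PR
    pptp_pd_rtv: float = 1.25            # final RTV above -> PD
    # rc: percent change at the final day
    rc_cr: float = -95.0
    rc_pr: float = -65.0
    rc_pd: float = 73.0

    def __post_init__(self) -> None:
        if not (self.npdxe_cr[0] < self.npdxe_pr[0] < self.npdxe_sd[0]):
            raise TrialDataError("npdxe best-response cutoffs must increase CR < PR < SD")
        if not (self.rc_cr < self.rc_pr < self.rc_pd):
            raise TrialDataError("rc cutoffs must increase CR < PR < PD")
        if self.pptp_measurable_mm3 < 0 or self.pptp_pr_rtv <= 0:
            raise TrialDataError("pptp cutoffs must be positive")


@dataclass
class ResponseCall:
    """Response level of one animal under one standard."""

    tumor_id: str
    arm: str
    animal_id: str
    standard: str
    level: str
    best_response: float | None = None
    best_avg_response: float | None = None
    metrics: dict = field(default_factory=dict)
    note: str = ""


@dataclass
class ArmResponseSummary:
    """Per-arm level counts and response indices."""

    tumor_id: str
    arm: str
    calls: list[ResponseCall]
    counts: dict[str, int]
    rr: float
    dcr: float

    @property
    def rr_pct(self) -> float:
        return round(self.rr * 100.0, 2)

    @property
    def dcr_pct(self) -> float:
        return round(self.dcr * 100.0, 2)


# ---------------------------------------------------------------------------
# trajectory metrics


def trajectories(ds: TrialDataset) -> list[AnimalTrajectory]:
    """Extract per-animal trajectories; animals without a usable baseline
    (day 0, volume > 0) are dropped with their ids in ``.skipped``."""
    out: list[AnimalTrajectory] = []
    skipped: list[tuple] = []
    for (tumor, arm, animal), g in ds.records.groupby(
        ["tumor_id", "arm", "animal_id"]
    ):
        g = g.sort_values("day")
        days = tuple(float(d) for d in g["day"])
        vols = tuple(float(v) for v in g["volume"])
        if days[0] != 0 or vols[0] <= 0:
            skipped.append((tumor, arm, animal))
            continue
        out.append(AnimalTrajectory(tumor, arm, animal, days, vols))
    trajectories.skipped = skipped  # type: ignore[attr-defined]
    return out


def delta_volume_pct(traj: AnimalTrajectory) -> pd.Series:
    """Percent volume change from baseline at each post-baseline day."""
    v0 = traj.volumes[0]
    days = np.array(traj.days[1:])
    vols = np.array(traj.volumes[1:])
    return pd.Series(100.0 * (vols - v0) / v0, index=days, name="delta_pct")


def best_response(traj: AnimalTrajectory, min_day: float = 10.0) -> float | None:
    """Minimum percent volume change over days at or past ``min_day``.

    Returns None when no measurement day is eligible (insufficient
    follow-up).
    """
    dv = delta_volume_pct(traj)
    eligible = dv[dv.index >= min_day]
    return None if eligible.empty else float(eligible.min())


def best_avg_response(traj: AnimalTrajectory, min_day: float = 10.0) -> float | None:
    """Minimum running mean of the percent change, over eligible days.

    For each eligible day t the mean of the percent change over all
    post-baseline days up to and including t is taken; the minimum of those
    running means is returned.  Day 0 (always 0%) is excluded from the mean.
    """
    dv = delta_volume_pct(traj)
    if dv.empty:
        return None
    running = dv.expanding().mean()
    eligible = running[running.index >= min_day]
    return None if eligible.empty else float(eligible.min())


# ---------------------------------------------------------------------------
# labeling standards


def label_npdxe(traj: AnimalTrajectory, th: Thresholds | None = None) -> ResponseCall:
    """PDX-encyclopedia labeling from BestResponse and BestAvgResponse.

    CR, PR and SD are tested in order against (best, best-average) cutoff
    pairs; anything else is PD.  Trajectories ending before the eligibility
    day cannot support the metrics and are called PD with an
    "insufficient follow-up" note.
    """
    th = th or Thresholds()
    best = best_response(traj, th.npdxe_min_day)
    best_avg = best_avg_response(traj, th.npdxe_min_day)
    if best is None or best_avg is None:
        return ResponseCall(
            traj.tumor_id, traj.arm, traj.animal_id, "npdxe", "PD",
            note="insufficient follow-up: no day at or past "
            f"{th.npdxe_min_day}",
        )
    for level, (b_cut, a_cut) in (
        ("CR", th.npdxe_cr),
        ("PR", th.npdxe_pr),
        ("SD", th.npdxe_sd),
    ):
        if best < b_cut and best_avg < a_cut:
            break
    else:
        level = "PD"
    return ResponseCall(
        traj.tumor_id, traj.arm, traj.animal_id, "npdxe", level,
        best_response=best, best_avg_response=best_avg,
        metrics={"best_response": best, "best_avg_response": best_avg},
    )


def label_pptp(traj: AnimalTrajectory, th: Thresholds | None = None) -> ResponseCall:
    """Pediatric-testing-program labeling on relative tumor volume.

    CR when the tumor ever drops below the measurable size; else PR when the
    minimum RTV reaches the regression cutoff; else PD when the final RTV
    exceeds the progression cutoff; else SD.  The measurable-size cutoff is
    the one criterion in this package expressed in absolute mm^3.
    """
    th = th or Thresholds()
    v0 = traj.volumes[0]
    rtv = np.array(traj.volumes) / v0
    vmin = min(traj.volumes)
    if vmin < th.pptp_measurable_mm3:
        level = "CR"
    elif rtv.min() <= th.pptp_pr_rtv:
        level = "PR"
    elif rtv[-1] > th.pptp_pd_rtv:
        level = "PD"
    else:
        level = "SD"
    end_pct = 100.0 * (rtv[-1] - 1.0)
    return ResponseCall(
        traj.tumor_id, traj.arm, traj.animal_id, "pptp", level,
        best_response=float(100.0 * (rtv.min() - 1.0)),
        metrics={"min_rtv": float(rtv.min()), "end_rtv": float(rtv[-1]),
                 "min_volume": float(vmin), "end_delta_pct": float(end_pct)},
    )


def label_rc(traj: AnimalTrajectory, th: Thresholds | None = None) -> ResponseCall:
    """Volume-adapted RECIST labeling on the final percent change."""
    th = th or Thresholds()
    dv = delta_volume_pct(traj)
    if dv.empty:
        return ResponseCall(
            traj.tumor_id, traj.arm, traj.animal_id, "rc", "PD",
            note="no post-baseline measurement",
        )
    end = float(dv.iloc[-1])
    if end <= th.rc_cr:
        level = "CR"
    elif end <= th.rc_pr:
        level = "PR"
    elif end >= th.rc_pd:
        level = "PD"
    else:
        level = "SD"
    return ResponseCall(
        traj.tumor_id, traj.arm, traj.animal_id, "rc", level,
        best_response=end, metrics={"end_delta_pct": end},
    )


_LABELERS = {"npdxe": label_npdxe, "pptp": label_pptp, "rc": label_rc}


def label_animal(
    traj: AnimalTrajectory, standard: str = "npdxe", th: Thresholds | None = None
) -> ResponseCall:
    if standard not in _LABELERS:
        raise TrialDataError(f"unknown standard {standard!r}; choose from {STANDARDS}")
    return _LABELERS[standard](traj, th)


def label_dataset(
    ds: TrialDataset, standard: str = "npdxe", th: Thresholds | None = None
) -> list[ResponseCall]:
    """Label every animal with a usable baseline."""
    return [label_animal(t, standard, th) for t in trajectories(ds)]


# ---------------------------------------------------------------------------
# arm-level indices


def arm_indices(calls: list[ResponseCall]) -> ArmResponseSummary:
    """RR and DCR of one arm from its animal-level calls."""
    if not calls:
        raise TrialDataError("no calls to summarize")
    tumors = {c.tumor_id for c in calls}
    arms = {c.arm for c in calls}
    if len(arms) > 1:
        raise TrialDataError(f"calls span multiple arms: {sorted(arms)}")
    counts = {lvl: sum(c.level == lvl for c in calls) for lvl in LEVELS}
    n = len(calls)
    rr = (counts["CR"] + counts["PR"]) / n
    dcr = (counts["CR"] + counts["PR"] + counts["SD"]) / n
    tumor = tumors.pop() if len(tumors) == 1 else "*"
    return ArmResponseSummary(
        tumor_id=tumor, arm=arms.pop(), calls=calls, counts=counts, rr=rr, dcr=dcr
    )


def summarize_responses(
    calls: list[ResponseCall], by_tumor: bool = False
) -> list[ArmResponseSummary]:
    """Group calls per arm (optionally per tumor-arm cell) and index each."""
    key = (lambda c: (c.tumor_id, c.arm)) if by_tumor else (lambda c: c.arm)
    groups: dict = {}
    for c in calls:
        groups.setdefault(key(c), []).append(c)
    return [arm_indices(v) for v in groups.values()]


def rank_arms(
    summaries: list[ArmResponseSummary], by: str = "dcr_then_rr"
) -> list[ArmResponseSummary]:
    """Order arms by efficacy, best first; ties fall back to the secondary
    index and then the arm name."""
    if by not in ("dcr_then_rr", "rr_then_dcr"):
        raise TrialDataError(f"unknown ranking {by!r}")
    if by == "dcr_then_rr":
        keyfun = lambda s: (-s.dcr, -s.rr, s.arm)
    else:
        keyfun = lambda s: (-s.rr, -s.dcr, s.arm)
    return sorted(summaries, key=keyfun)


def calls_table(calls: list[ResponseCall]) -> pd.DataFrame:
    rows = [
        {
            "tumor_id": c.tumor_id,
            "arm": c.arm,
            "animal_id": c.animal_id,
            "standard": c.standard,
            "level": c.level,
            "best_response": c.best_response,
            "best_avg_response": c.best_avg_response,
            "note": c.note,
        }
        for c in calls
    ]
    return pd.DataFrame(rows)
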