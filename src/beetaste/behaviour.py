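"""Visit-level scoring for free-flight preference and conditioning assays.

Preference assay: each landing either favours tastant-treated flowers
(probing a treated flower, or leaving an untreated one without probing) or
does not.  A bee's tastant surface response rate is the proportion of its
landings favouring treated flowers; random foraging gives 0.5.

Differential conditioning: a visit is correct when the bee probes a
rewarding flower or leaves a non-rewarding one.  The success rate (the
proportion of correct visits) is computed over consecutive ten-visit
intervals of the 70-visit training phase and over the 20-visit test phase.

Proportions are arcsine square-root transformed (asin(sqrt(p))) for the
downstream statistics; 0.5 transforms to pi/4 ~ 0.79.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BeeSummary",
    "classify_preference_visit",
    "classify_conditioning_visit",
    "tastant_response_rate",
    "success_curve",
    "arcsine_sqrt",
    "summarize_preference_log",
    "summarize_conditioning_log",
]

TRAINING_VISITS = 70
TEST_VISITS = 20
INTERVAL = 10


@dataclass
class BeeSummary:
    """Per-bee derived scores, raw and arcsine-sqrt transformed."""

    bee_id: str
    group: str
    response_rate: float | None = None
    success_by_interval: np.ndarray | None = None  # at visits 10, 20, ..., 70
    test_success: float | None = None
    n_mouthpart_contacts: int = 0

    @property
    def response_rate_t(self) -> float | None:
        return None if self.response_rate is None else arcsine_sqrt(self.response_rate)

    @property
    def success_by_interval_t(self) -> np.ndarray | None:
        if self.success_by_interval is None:
            return None
        return arcsine_sqrt(self.success_by_interval)

    @property
    def test_success_t(self) -> float | None:
        return None if self.test_success is None else arcsine_sqrt(self.test_success)


def arcsine_sqrt(p):
    """Variance-stabilizing transform for proportions: asin(sqrt(p)).

    Maps [0, 1] onto [0, pi/2]; 0.5 -> pi/4 (0.785, printed as 0.79).
    """
    arr = np.asarray(p, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    out = np.arcsin(np.sqrt(arr))
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


def classify_preference_visit(flower_class: str, probed: bool) -> str:
    """'favouring' iff (treated and probed) or (untreated and not probed)."""
    if flower_class not in ("treated", "untreated"):
        raise ValueError(
            f"preference visits need flower_class treated/untreated, got {flower_class!r}"
        )
    favour = (flower_class == "treated") == bool(probed)
    return "favouring" if favour else "not_favouring"


def classify_conditioning_visit(flower_class: str, probed: bool) -> str:
    """'correct' iff (rewarding and probed) or (nonrewarding and not probed)."""
    if flower_class not in ("rewarding", "nonrewarding"):
        raise ValueError(
            "conditioning visits need flower_class rewarding/nonrewarding, "
            f"got {flower_class!r}"
        )
    correct = (flower_class == "rewarding") == bool(probed)
    return "correct" if correct else "incorrect"


def _one_bee(visits: pd.DataFrame) -> None:
    if visits.empty:
        raise ValueError("empty visit log")
    if visits["bee_id"].nunique() != 1:
        raise ValueError("expected visits from exactly one bee")


def tastant_response_rate(visits: pd.DataFrame) -> float:
    """Proportion of one bee's landings favouring treated flowers."""
    _one_bee(visits)
    labels = [
        classify_preference_visit(c, p)
        for c, p in zip(visits["flower_class"], visits["probed"])
    ]
    return sum(lab == "favouring" for lab in labels) / len(labels)


def success_curve(visits: pd.DataFrame) -> BeeSummary:
    """Success rates for one bee's full conditioning log.

    Returns seven training-interval values (success over visits 1-10,
    11-20, ..., 61-70) and the success rate over the 20 test visits.
    Incomplete logs fail loudly, mirroring the exclusion of bees that did
    not complete the experiment.
    """
    _one_bee(visits)
    bee = visits["bee_id"].iloc[0]
    group = visits["group"].iloc[0] if "group" in visits else ""
    train = visits[visits["phase"] == "training"].sort_values("visit_index")
    test = visits[visits["phase"] == "test"].sort_values("visit_index")

    expected = set(range(1, TRAINING_VISITS + 1))
    missing = sorted(expected - set(train["visit_index"]))
    if missing:
        raise ValueError(f"incomplete training log for {bee}: missing visits {missing}")
    if len(test) != TEST_VISITS:
        raise ValueError(
            f"incomplete test log for {bee}: expected {TEST_VISITS} visits, got {len(test)}"
        )

    correct = np.array(
        [
            classify_conditioning_visit(c, p) == "correct"
            for c, p in zip(train["flower_class"], train["probed"])
        ],
        dtype=float,
    )
    intervals = correct[: TRAINING_VISITS].reshape(-1, INTERVAL).mean(axis=1)
    test_correct = np.array(
        [
            classify_conditioning_visit(c, p) == "correct"
            for c, p in zip(test["flower_class"], test["probed"])
        ],
        dtype=float,
    )
    n_mouth = int(visits["mouthpart_contact"].sum()) if "mouthpart_contact" in visits else 0
    return BeeSummary(
        bee_id=bee,
        group=group,
        success_by_interval=intervals,
        test_success=float(test_correct.mean()),
        n_mouthpart_contacts=n_mouth,
    )


def summarize_preference_log(visits: pd.DataFrame) -> pd.DataFrame:
    """One row per bee: response rate plus its transform.

    Mouthpart-contact visits are scored normally but counted in a separate
    column so rare oral-taste opportunities stay visible in reports.
    """
    rows = []
    for bee, grp in visits.groupby("bee_id", sort=True):
        rr = tastant_response_rate(grp)
        rows.append(
            {
                "bee_id": bee,
                "group": grp["group"].iloc[0] if "group" in grp else "",
                "rr": rr,
                "rr_t": arcsine_sqrt(rr),
                "n_mouthpart": int(grp["mouthpart_contact"].sum())
                if "mouthpart_contact" in grp
                else 0,
            }
        )
    return pd.DataFrame(rows)


def summarize_conditioning_log(visits: pd.DataFrame) -> pd.DataFrame:
    """One row per bee: s10..s70, test success, and their transforms."""
    rows = []
    for bee, grp in visits.groupby("bee_id", sort=True):
        s = success_curve(grp)
        row = {"bee_id": bee, "group": s.group}
        for k, val in enumerate(s.success_by_interval, start=1):
            row[f"s{k * 10}"] = val
        row["test"] = s.test_success
        for k, val in enumerate(s.success_by_interval_t, start=1):
            row[f"s{k * 10}_t"] = val
        row["test_t"] = s.test_success_t
        row["n_mouthpart"] = s.n_mouthpart_contacts
        rows.append(row)
    return pd.DataFrame(rows)
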