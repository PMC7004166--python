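"""Scoring decoded musth days against field observations.

A field sighting labels the day before, the day of, and the day after
the observation with the observed state (the bull is assumed to hold its
state across adjacent days). When a musth and a non-musth observation
both claim a day, a same-day observation wins; otherwise the day is
dropped as conflicted. Sensitivity and specificity are reported both
pooled over all labelled days and as the mean of per-individual values
(the primary aggregation, since individuals contribute very different
numbers of observation days).
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trackio import LABEL_EXCLUDED, LABEL_MUSTH, LABEL_NON_MUSTH

logger = logging.getLogger(__name__)

_ONE_DAY = dt.timedelta(days=1)


def expand_labels(observations: pd.DataFrame) -> pd.DataFrame:
    """Expand each usable observation to daily labels on d-1, d, d+1.

    Returns columns individual_id, date, label (musth / non_musth).
    Excluded (single-signal) observations are skipped entirely.
    """
    obs = observations[observations["label"] != LABEL_EXCLUDED]
    claims: dict[tuple, dict] = {}
    for row in obs.itertuples(index=False):
        for off, same_day in ((-1, False), (0, True), (1, False)):
            key = (row.individual_id, row.date + off * _ONE_DAY)
            rec = claims.setdefault(key, {})
            if same_day:
                rec["same"] = row.label
            else:
                rec.setdefault("adj", set()).add(row.label)
    rows = []
    for (ind, date), rec in sorted(claims.items()):
        if "same" in rec:
            label = rec["same"]
        else:
            adj = rec.get("adj", set())
            if len(adj) != 1:
                logger.warning("conflicting labels for %s on %s; day dropped",
                               ind, date)
                continue
            label = next(iter(adj))
        rows.append({"individual_id": ind, "date": date, "label": label})
    return pd.DataFrame(rows, columns=["individual_id", "date", "label"])


@dataclass
class ConfusionSummary:
    per_individual: pd.DataFrame  # id, tp, fp, tn, fn, sensitivity, specificity
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n_days(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def pooled_sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else np.nan

    @property
    def pooled_specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else np.nan

    @property
    def pooled_accuracy(self) -> float:
        return (self.tp + self.tn) / self.n_days if self.n_days else np.nan

    @property
    def mean_sensitivity(self) -> float:
        """Mean of per-individual sensitivities (primary aggregation)."""
        s = self.per_individual["sensitivity"].dropna()
        return float(s.mean()) if len(s) else np.nan

    @property
    def mean_specificity(self) -> float:
        s = self.per_individual["specificity"].dropna()
        return float(s.mean()) if len(s) else np.nan

    def to_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
                "pooled_sensitivity": self.pooled_sensitivity,
                "pooled_specificity": self.pooled_specificity,
                "pooled_accuracy": self.pooled_accuracy,
                "mean_sensitivity": self.mean_sensitivity,
                "mean_specificity": self.mean_specificity}


def confusion(decoded: pd.DataFrame, labels: pd.DataFrame) -> ConfusionSummary:
    """Confusion counts of decoded musth days against labelled days.

    ``decoded``: columns individual_id, date, assigned (bool musth call).
    ``labels``: output of :func:`expand_labels`. Only dates present in
    both tables are scored.
    """
    merged = labels.merge(decoded, on=["individual_id", "date"], how="inner")
    if merged.empty:
        raise ValueError("no labelled days overlap the decoded days")
    truth = merged["label"] == LABEL_MUSTH
    call = merged["assigned"].astype(bool)
    merged["tp"] = truth & call
    merged["fp"] = ~truth & call
    merged["tn"] = ~truth & ~call
    merged["fn"] = truth & ~call
    per = merged.groupby("individual_id")[["tp", "fp", "tn", "fn"]].sum()
    per["sensitivity"] = per["tp"] / (per["tp"] + per["fn"]).replace(0, np.nan)
    per["specificity"] = per["tn"] / (per["tn"] + per["fp"]).replace(0, np.nan)
    per = per.reset_index()
    return ConfusionSummary(per_individual=per,
                            tp=int(per["tp"].sum()), fp=int(per["fp"].sum()),
                            tn=int(per["tn"].sum()), fn=int(per["fn"].sum()))
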