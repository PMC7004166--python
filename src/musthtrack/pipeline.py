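"""End-to-end orchestration: tracks -> metrics -> labels -> detection -> scores.

These helpers glue the module stages together the way the command-line
pipeline runs them; each stage remains individually usable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import covariates as cov
from .daily_metrics import compute_daily_metrics
from .evaluate import ConfusionSummary, confusion, expand_labels
from .musth_hmm import (HmmConfig, SCALED_CONFIG, WindowSelectionError,
                        decode_states, sample_posterior, select_window)
from .preprocess import regularize
from .trackio import Track

logger = logging.getLogger(__name__)


def daily_table(tracks: dict[str, Track], stack=None,
                ages: dict[str, float] | None = None) -> pd.DataFrame:
    """Regularise every track and compute per-day metrics (+ covariates)."""
    frames = []
    for ind, tr in tracks.items():
        rt = regularize(tr)
        dm = compute_daily_metrics(rt)
        if dm.empty:
            continue
        if stack is not None:
            per_fix = cov.sample_covariates(rt, stack)
            dm = dm.merge(cov.daily_covariate_means(per_fix),
                          on=["individual_id", "date"], how="left")
        if ages is not None and ind in ages:
            dm["age"] = float(ages[ind])
        frames.append(dm)
    if not frames:
        return pd.DataFrame()
    return pd.concat(frames, ignore_index=True)


def attach_labels(daily: pd.DataFrame, observations: pd.DataFrame) -> pd.DataFrame:
    """Restrict the daily table to labelled days and add a 0/1 musth column.

    `observations` must already carry a label column (see
    :func:`musthtrack.trackio.label_observations`); labels are expanded to
    the day before and after each sighting.
    """
    labels = expand_labels(observations)
    merged = daily.merge(labels, on=["individual_id", "date"], how="inner")
    merged["musth"] = (merged["label"] == "musth").astype(float)
    return merged.drop(columns=["label"])


@dataclass
class DetectionResult:
    windows: dict = field(default_factory=dict)     # id -> HmmWindow
    posteriors: dict = field(default_factory=dict)  # id -> HmmPosterior
    decodes: dict = field(default_factory=dict)     # id -> DecodeResult
    rejections: dict = field(default_factory=dict)  # id -> reason
    confusion: ConfusionSummary | None = None


def detect_musth(daily: pd.DataFrame, observations: pd.DataFrame,
                 response: str = "speed",
                 config: HmmConfig | None = None,
                 decode_seed: int = 0) -> DetectionResult:
    """Select a window per eligible individual, sample the HMM posterior,
    decode musth days, and score them against the expanded labels."""
    cfg = config or SCALED_CONFIG
    res = DetectionResult()
    decoded_rows = []
    for ind in sorted(daily["individual_id"].unique()):
        try:
            w = select_window(daily, observations, ind, response=response)
        except WindowSelectionError as e:
            res.rejections[ind] = str(e)
            logger.info("window rejected: %s", e)
            continue
        post = sample_posterior(w, config=cfg)
        if not post.converged:
            logger.warning("%s: R-hat > 1.1, posterior flagged non-converged", ind)
        dec = decode_states(post, w, seed=decode_seed)
        res.windows[ind] = w
        res.posteriors[ind] = post
        res.decodes[ind] = dec
        df = dec.as_frame()
        df.insert(0, "individual_id", ind)
        decoded_rows.append(df)
    if decoded_rows:
        decoded = pd.concat(decoded_rows, ignore_index=True)
        labels = expand_labels(observations)
        try:
            res.confusion = confusion(decoded, labels)
        except ValueError:
            res.confusion = None
    return res
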