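"""FRET tension-sensor readout.

A vinculin tension sensor loses FRET under load: the acceptor/donor
emission ratio (YFP transfer ratio) falls as the molecule opens, so the
reciprocal ratio (donor/acceptor) is proportional to tension.  This module
turns per-adhesion donor/acceptor series into per-track tension summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

__all__ = ["TensionRecord", "fret_ratio", "track_tension_summary", "summarize_tension"]


@dataclass
class TensionRecord:
    """Per-frame FRET readout of one adhesion track.

    ``yfp_ratio`` is acceptor/donor; ``tension_index`` its reciprocal.
    Frames where either background-subtracted channel is non-positive are
    masked and counted in ``n_masked``.
    """

    track_id: int
    donor: np.ndarray
    acceptor: np.ndarray
    yfp_ratio: np.ndarray = field(init=False)
    tension_index: np.ndarray = field(init=False)
    n_masked: int = field(init=False)

    def __post_init__(self) -> None:
        donor = np.asarray(self.donor, dtype=float)
        acceptor = np.asarray(self.acceptor, dtype=float)
        if donor.shape != acceptor.shape:
            raise ValueError("donor and acceptor series must align")
        valid = (donor > 0) & (acceptor > 0)
        self.n_masked = int((~valid).sum())
        if self.n_masked:
            warnings.warn(
                f"track {self.track_id}: masked {self.n_masked} frames with "
                "non-positive channel intensity"
            )
        self.donor = donor[valid]
        self.acceptor = acceptor[valid]
        self.yfp_ratio = self.acceptor / self.donor
        self.tension_index = 1.0 / self.yfp_ratio

    @property
    def mean_tension(self) -> float:
        return float(self.tension_index.mean())

    @property
    def min_tension(self) -> float:
        return float(self.tension_index.min())


def fret_ratio(donor, acceptor):
    """Acceptor/donor transfer ratio (elementwise); reciprocal ~ tension.

    Non-positive donor values yield NaN with a warning.
    """
    donor = np.asarray(donor, dtype=float)
    acceptor = np.asarray(acceptor, dtype=float)
    bad = donor <= 0
    if np.any(bad):
        warnings.warn(f"masked {int(np.sum(bad))} non-positive donor values")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(bad, np.nan, acceptor / np.where(bad, 1.0, donor))
    return float(out) if out.ndim == 0 else out


def track_tension_summary(record: TensionRecord) -> Tuple[float, float]:
    """(mean_tension, min_tension) of the retained frames."""
    if record.tension_index.size == 0:
        raise ValueError("no retained frames in track")
    return record.mean_tension, record.min_tension


def summarize_tension(
    series: pd.DataFrame,
    donor_background: float = 0.0,
    acceptor_background: float = 0.0,
) -> pd.DataFrame:
    """Per-track tension summary from a (track_id, donor, acceptor) table.

    Backgrounds are subtracted per channel before the ratio; frames where
    either channel falls to or below background are masked.
    """
    rows = []
    for tid, grp in series.groupby("track_id", sort=True):
        rec = TensionRecord(
            int(tid),
            grp["donor"].to_numpy() - donor_background,
            grp["acceptor"].to_numpy() - acceptor_background,
        )
        if rec.tension_index.size == 0:
            continue
        rows.append(
            {
                "track_id": int(tid),
                "n_frames": int(rec.tension_index.size),
                "n_masked": rec.n_masked,
                "mean_yfp_ratio": float(rec.yfp_ratio.mean()),
                "mean_tension": rec.mean_tension,
                "min_tension": rec.min_tension,
            }
        )
    return pd.DataFrame(rows)
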