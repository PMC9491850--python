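"""Mean impact value (MIV) variable importance for trained regression models.

Each input variable is perturbed by +/- a fixed fraction (default 10%) of its
value; the per-sample difference between the two perturbed predictions is the
impact value (IV), and its mean over samples is the MIV.  |MIV| normalized to
sum 1 gives relative contributions; variables are ranked by |MIV| and the
smallest prefix whose cumulative contribution reaches a cutoff (default 90%)
is selected.

For muscle-level importance the perturbation is applied to a raw recording
channel *before* windowing/reduction, so contributions attach to muscles even
when the model consumes derived inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .synth import Recording
from .windows import WindowedDataset

__all__ = ["MivReport", "compute_miv", "select_variables", "muscle_miv",
           "muscle_contribution_table"]


@dataclass
class MivReport:
    """Per-variable impact values, normalized contributions and selection."""

    iv_per_sample: np.ndarray       # (n_samples, n_vars) A1 - A2
    miv: np.ndarray                 # (n_vars,)
    abs_normalized: np.ndarray      # |miv| / sum|miv| (zeros if all-zero)
    ranking: np.ndarray             # variable indices by |miv| descending
    selected: np.ndarray            # prefix of ranking reaching the cutoff
    perturbation: float
    cutoff: float
    names: tuple[str, ...] = ()
    degenerate: bool = False        # all-zero MIV (flat prediction function)

    def to_frame(self) -> pd.DataFrame:
        names = self.names or tuple(f"x{i}" for i in range(len(self.miv)))
        rank_of = np.empty(len(self.miv), dtype=int)
        rank_of[self.ranking] = np.arange(1, len(self.miv) + 1)
        return pd.DataFrame({
            "variable": names,
            "miv": self.miv,
            "abs_normalized": self.abs_normalized,
            "rank": rank_of,
            "selected": np.isin(np.arange(len(self.miv)), self.selected),
        })


def _finish_report(iv: np.ndarray, perturbation: float, cutoff: float,
                   names: Sequence[str]) -> MivReport:
    miv = iv.mean(axis=0)
    abs_miv = np.abs(miv)
    total = abs_miv.sum()
    degenerate = total == 0.0
    if degenerate:
        warnings.warn("all-zero MIV: prediction function is insensitive to "
                      "every variable at this perturbation", stacklevel=3)
        norm = np.zeros_like(abs_miv)
    else:
        norm = abs_miv / total
    ranking = np.argsort(-abs_miv, kind="stable")
    report = MivReport(iv_per_sample=iv, miv=miv, abs_normalized=norm,
                       ranking=ranking, selected=np.empty(0, dtype=int),
                       perturbation=perturbation, cutoff=cutoff,
                       names=tuple(names), degenerate=degenerate)
    report.selected = select_variables(report)
    return report


def compute_miv(model_predict_fn: Callable[[np.ndarray], np.ndarray],
                X: np.ndarray, perturbation: float = 0.10, *,
                cutoff: float = 0.90,
                names: Sequence[str] = (),
                groups: Sequence[np.ndarray] | None = None) -> MivReport:
    """MIV of each input variable (or column group) of a prediction function.

    For variable j, sample matrix P1 scales column j by (1 + p) and P2 by
    (1 - p); IV_j = predict(P1) - predict(P2) per sample.  ``groups`` maps
    each logical variable to a set of columns scaled together (e.g. all
    window samples of one raw channel).
    """
    X = np.asarray(X, dtype=float)
    if perturbation < 0:
        raise ValueError("perturbation must be >= 0")
    if groups is None:
        groups = [np.array([j]) for j in range(X.shape[1])]
    iv = np.empty((len(X), len(groups)))
    for j, cols in enumerate(groups):
        up, down = X.copy(), X.copy()
        up[:, cols] *= 1.0 + perturbation
        down[:, cols] *= 1.0 - perturbation
        iv[:, j] = np.asarray(model_predict_fn(up)) - np.asarray(model_predict_fn(down))
    return _finish_report(iv, perturbation, cutoff, names)


def select_variables(report: MivReport) -> np.ndarray:
    """Smallest prefix of the ranking whose cumulative |MIV| share >= cutoff.

    Variables with zero MIV are never selected; with ``cutoff=1.0`` all
    non-zero-MIV variables are selected.
    """
    if report.degenerate:
        return np.empty(0, dtype=int)
    shares = report.abs_normalized[report.ranking]
    cum = np.cumsum(shares)
    k = int(np.searchsorted(cum, report.cutoff - 1e-12) + 1)
    k = min(k, int(np.count_nonzero(shares)))
    return report.ranking[:k].copy()


def muscle_miv(predict_dataset_fn: Callable[[WindowedDataset], np.ndarray],
               recording: Recording,
               make_dataset_fn: Callable[[Recording], WindowedDataset],
               perturbation: float = 0.10, cutoff: float = 0.90) -> MivReport:
    """MIV per muscle channel, perturbing the raw signal before windowing.

    Channel c of the recording is scaled by (1 +/- p), the full
    windowing/reduction transform re-applied, and the model evaluated; this
    attaches importance to muscles rather than to derived input columns.
    """
    iv_cols = []
    for c in range(recording.n_channels):
        preds = []
        for factor in (1.0 + perturbation, 1.0 - perturbation):
            sig = recording.signals.copy()
            sig[:, c] *= factor
            rec = Recording(signals=sig, force=recording.force,
                            fs=recording.fs, labels=recording.labels,
                            truth=recording.truth)
            preds.append(np.asarray(predict_dataset_fn(make_dataset_fn(rec))))
        iv_cols.append(preds[0] - preds[1])
    iv = np.column_stack(iv_cols)
    return _finish_report(iv, perturbation, cutoff, recording.labels)


def muscle_contribution_table(reports: Mapping[str, MivReport]) -> pd.DataFrame:
    """Task x muscle matrix of normalized |MIV| contributions (rows sum to 1)."""
    if not reports:
        raise ValueError("no reports given")
    first = next(iter(reports.values()))
    cols = first.names or tuple(f"x{i}" for i in range(len(first.miv)))
    rows = {}
    for task, rep in reports.items():
        names = rep.names or cols
        if tuple(names) != tuple(cols):
            raise ValueError("reports have inconsistent variable names")
        rows[task] = rep.abs_normalized
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(cols))
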