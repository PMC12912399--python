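"""Cross-activity aggregation and ranking of facial ROIs.

For every activity the per-ROI metrics (median over participants, after
optionally pooling the rPPG methods) are min-max normalized into an overall
score; summing the scores across activities and sorting descending produces
the ROI ranking.  The stacked-bar report shows each ROI's summed score with
its per-activity contributions.

The "top group" annotation is a reproducible stand-in for drawing a box
around the leading ROIs by eye: it is the prefix of the ranking ending at
the first consecutive summed-score gap larger than a configurable
threshold, and is advisory only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .metrics import overall_score

REQUIRED_COLUMNS = ("roi_index", "roi_name", "activity", "participant", "method",
                    "mae", "pcc", "snr")
#: consecutive summed-OS gap that closes the advisory top group
TOP_GAP_THRESHOLD = 0.3


@dataclass
class RankingResult:
    """Ordered ROI ranking with per-activity score components."""

    table: pd.DataFrame  # rank, roi_index, roi_name, os_<activity>..., os_sum, in_top_group
    activities: tuple[str, ...]
    method_combination: str
    top_gap_threshold: float
    excluded_rois: tuple[int, ...] = field(default_factory=tuple)

    @property
    def order(self) -> list[int]:
        return self.table["roi_index"].tolist()

    @property
    def top_group(self) -> list[int]:
        return self.table.loc[self.table["in_top_group"], "roi_index"].tolist()


def aggregate_and_rank(
    records: pd.DataFrame,
    activities: tuple[str, ...] | None = None,
    combine: str = "mean",
    top_gap_threshold: float = TOP_GAP_THRESHOLD,
    renormalize: bool = False,
) -> RankingResult:
    """Aggregate per-recording metrics into the cross-activity ROI ranking.

    Per method and activity, each ROI's MAE/PCC/SNR is the median over
    participants; the overall score is computed per activity and, with
    ``combine="mean"`` (the default), averaged over the rPPG methods before
    summing across activities.  ROIs missing any (activity, method) cell are
    excluded with a warning.  Ties in the summed score break by lower
    aggregated MAE, then by ROI index.

    ``renormalize`` optionally rescales each activity's combined scores back
    onto [0, 1] after method pooling.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise InputError(f"records missing columns: {missing}")
    if combine not in ("mean", "per-method"):
        raise InputError("combine must be 'mean' or 'per-method'")
    records = records.copy()
    if activities is None:
        activities = tuple(sorted(records["activity"].unique()))
    methods = tuple(sorted(records["method"].unique()))

    all_rois = sorted(records["roi_index"].unique())
    cells = records.groupby(["roi_index", "activity", "method"]).size()
    complete = [
        k for k in all_rois
        if all((k, a, m) in cells.index for a in activities for m in methods)
    ]
    excluded = tuple(k for k in all_rois if k not in complete)
    if excluded:
        warnings.warn(
            f"ROIs {excluded} lack records for some (activity, method) cell "
            "and are excluded from the ranking",
            stacklevel=2,
        )
    records = records[records["roi_index"].isin(complete)]
    if records.empty or len(complete) < 2:
        raise InputError("need >= 2 ROIs with complete records")

    names = records.groupby("roi_index")["roi_name"].first()
    per_activity = {}
    for a in activities:
        per_method = []
        for m in methods:
            sub = records[(records["activity"] == a) & (records["method"] == m)]
            agg = sub.groupby("roi_index")[["mae", "pcc", "snr"]].median()
            per_method.append(overall_score(agg))
        os_a = pd.concat(per_method, axis=1).mean(axis=1)
        if renormalize and os_a.max() > os_a.min():
            os_a = (os_a - os_a.min()) / (os_a.max() - os_a.min())
        per_activity[a] = os_a

    frame = pd.DataFrame({f"os_{a}": per_activity[a] for a in activities})
    frame["os_sum"] = frame.sum(axis=1)
    frame["agg_mae"] = records.groupby(["roi_index", "activity", "method"])["mae"] \
        .median().groupby("roi_index").mean()
    frame["roi_name"] = names
    frame = frame.sort_values(
        by=["os_sum", "agg_mae", "roi_index"], ascending=[False, True, True],
        kind="mergesort",
    ).reset_index().rename(columns={"roi_index": "roi_index"})
    frame.insert(0, "rank", np.arange(1, len(frame) + 1))

    gaps = -np.diff(frame["os_sum"].to_numpy())
    in_top = np.zeros(len(frame), dtype=bool)
    big = np.flatnonzero(gaps > top_gap_threshold)
    if big.size:
        in_top[: big[0] + 1] = True
    frame["in_top_group"] = in_top

    cols = ["rank", "roi_index", "roi_name"] + [f"os_{a}" for a in activities] + \
           ["os_sum", "in_top_group"]
    return RankingResult(
        frame[cols], tuple(activities),
        "mean_over_methods" if combine == "mean" else "per_method",
        top_gap_threshold, excluded,
    )


def export_report(result: RankingResult, destination) -> dict[str, Path]:
    """Write ranking CSV, metadata JSON and the stacked-bar figure.

    Outputs are deterministic for identical inputs.
    """
    dest = Path(destination)
    try:
        dest.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise InputError(f"cannot create report directory {dest}: {exc}") from exc
    if result.table.empty:
        raise InputError("empty ranking result")

    csv_path = dest / "ranking.csv"
    result.table.to_csv(csv_path, index=False, float_format="%.6f")

    meta_path = dest / "ranking_metadata.json"
    meta = {
        "activities": list(result.activities),
        "method_combination": result.method_combination,
        "top_gap_threshold": result.top_gap_threshold,
        "top_group_roi_indices": result.top_group,
        "excluded_rois": list(result.excluded_rois),
        "n_rois": int(len(result.table)),
    }
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True))

    fig_path = dest / "ranking_stacked_os.png"
    _stacked_bar(result, fig_path)
    return {"csv": csv_path, "metadata": meta_path, "figure": fig_path}


def _stacked_bar(result: RankingResult, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    tab = result.table
    x = np.arange(len(tab))
    fig, ax = plt.subplots(figsize=(max(8, 0.4 * len(tab)), 4.5))
    bottom = np.zeros(len(tab))
    for a in result.activities:
        vals = tab[f"os_{a}"].to_numpy()
        ax.bar(x, vals, bottom=bottom, label=a)
        bottom += vals
    if tab["in_top_group"].any():
        edge = int(tab["in_top_group"].sum()) - 0.5
        ax.axvline(edge, color="green", linestyle="--", linewidth=1)
    ax.set_xticks(x)
    ax.set_xticklabels(tab["roi_name"], rotation=75, ha="right", fontsize=7)
    ax.set_ylabel("summed overall score")
    ax.legend(title="activity", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
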