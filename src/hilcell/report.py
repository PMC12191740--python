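"""Final-model application and evaluation artifacts.

Covers the candidate-triage endpoint of the pipeline: propose CTC
candidates above a probability threshold, collapse duplicates, report
positive predictive value (PPV) against expert review, and summarize
human-in-the-loop run trajectories as tidy tables and plots.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import ClassifierModel, Prediction, predict, remove_duplicates
from .hil import TOTAL, RunResult


@dataclass
class CandidateSet:
    """Deduplicated above-threshold CTC candidates, ordered by probability."""

    candidates: list[Prediction]
    centroids: list[tuple[float, float]]
    threshold: float
    sample_tag: str = ""

    def __len__(self) -> int:
        return len(self.candidates)

    @property
    def ids(self) -> list[str]:
        return [c.id for c in self.candidates]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [c.id for c in self.candidates],
                "prob": [c.prob_positive for c in self.candidates],
                "centroid_row": [c[0] for c in self.centroids],
                "centroid_col": [c[1] for c in self.centroids],
                "sample": self.sample_tag,
            }
        )


@dataclass(frozen=True)
class PPVRecord:
    suggested: int
    actual: int

    def __post_init__(self) -> None:
        if not 0 <= self.actual <= self.suggested:
            raise ValueError("need 0 <= actual <= suggested")

    @property
    def ppv(self) -> float | None:
        if self.suggested == 0:
            return None
        return self.actual / self.suggested


def ppv(actual: int, suggested: int) -> float | None:
    """Positive predictive value actual/suggested; None when nothing suggested."""
    return PPVRecord(suggested=suggested, actual=actual).ppv


def propose_candidates(
    model: ClassifierModel,
    features: np.ndarray,
    ids: Sequence[str],
    centroids: Sequence[tuple[float, float]],
    threshold: float = 0.5,
    dedup_radius: float = 5.0,
    sample_tag: str = "",
) -> CandidateSet:
    """Predict, keep prob > threshold, dedup by centroid proximity.

    Candidates are returned in descending probability order, the order an
    expert would review them in.
    """
    preds = predict(model, features, ids=ids, threshold=threshold)
    keep = [k for k, p in enumerate(preds) if p.prob_positive > threshold]
    kept_preds = [preds[k] for k in keep]
    kept_centroids = [tuple(centroids[k]) for k in keep]
    survivors = remove_duplicates(kept_preds, kept_centroids, dedup_radius)
    surv_ids = {p.id for p in survivors}
    pairs = [
        (p, c) for p, c in zip(kept_preds, kept_centroids) if p.id in surv_ids
    ]
    pairs.sort(key=lambda pc: (-pc[0].prob_positive, pc[0].id))
    return CandidateSet(
        candidates=[p for p, _ in pairs],
        centroids=[c for _, c in pairs],
        threshold=threshold,
        sample_tag=sample_tag,
    )


def tidy_results(results: Sequence[RunResult]) -> pd.DataFrame:
    """Flatten run results into (seed, arm, loop, stratum, f1) rows."""
    if not results:
        raise ValueError("no results to summarize")
    rows = []
    for res in results:
        for rec in res.loops:
            rows.append(
                {
                    "seed": res.seed,
                    "arm": res.arm,
                    "loop": rec.loop,
                    "stratum": TOTAL,
                    "f1": rec.overall_f1,
                }
            )
            for stratum, f1 in rec.f1_by_stratum.items():
                rows.append(
                    {
                        "seed": res.seed,
                        "arm": res.arm,
                        "loop": rec.loop,
                        "stratum": stratum,
                        "f1": f1,
                    }
                )
    return pd.DataFrame(rows)


def summarize_runs(results: Sequence[RunResult]) -> pd.DataFrame:
    """Mean and SD of F1 across seeds, per (arm, loop, stratum).

    All runs must share one loop structure; mixing configurations in one
    summary is refused.
    """
    tidy = tidy_results(results)
    n_loops = tidy.groupby(["seed", "arm"])["loop"].max()
    if n_loops.nunique() > 1:
        raise ValueError("results mix different loop counts; summarize separately")
    out = (
        tidy.groupby(["arm", "loop", "stratum"], sort=True)["f1"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    out["sd"] = out["sd"].fillna(0.0)
    return out


def plot_trajectories(summary: pd.DataFrame, out_path, stratum=TOTAL) -> None:
    """Mean +- SD F1 trajectory per arm for one stratum, as a PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    sub = summary[summary["stratum"] == stratum]
    for arm, grp in sub.groupby("arm"):
        grp = grp.sort_values("loop")
        ax.errorbar(
            grp["loop"], grp["mean"], yerr=grp["sd"], marker="o",
            capsize=3, label=arm,
        )
    ax.set_xlabel("HiL loop")
    ax.set_ylabel("F1 score")
    ax.set_title(f"stratum: {stratum}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def ppv_table(records: dict[str, PPVRecord]) -> pd.DataFrame:
    """Per-sample PPV table (3 decimals) with a recomputed totals row."""
    rows = []
    for tag, rec in sorted(records.items()):
        rows.append(
            {
                "sample": tag,
                "suggested": rec.suggested,
                "actual": rec.actual,
                "ppv": None if rec.ppv is None else round(rec.ppv, 3),
            }
        )
    total_suggested = sum(r["suggested"] for r in rows)
    total_actual = sum(r["actual"] for r in rows)
    total_ppv = (
        round(total_actual / total_suggested, 3) if total_suggested else None
    )
    rows.append(
        {
            "sample": "total",
            "suggested": total_suggested,
            "actual": total_actual,
            "ppv": total_ppv,
        }
    )
    return pd.DataFrame(rows)
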