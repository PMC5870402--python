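"""Vaccine-response analysis recipe: preprocessing and an end-to-end pipeline.

In the influenza-vaccination application, the predictor block is built from
genomewide expression *difference scores* — the day-3 post-vaccination
expression minus the pre-vaccination baseline, per probeset, then centered
and scaled to sum of squares one.  The outcome is the maximal
baseline-corrected log hemagglutination-inhibition (HAI) antibody titer
change across three assay types, centered (taking the maximum dampens the
influence of subjects who start with high titers from previous infections).
The outcome is centered only, not scaled, for this recipe.

The recipe itself — two components, alpha = 0.99, ridge at 5% of the lasso,
stability selection with N = 500 resamples, pi_thr = 0.90 and E(V) = 1 —
runs on any matched expression/titer input; no data are downloaded here (the
public accessions are carried as provenance strings only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import PenaltySettings, ScaledBlock, center_scale
from .sparse import FitOptions
from .stability import StabilityResult, StabilitySettings, run_stability_selection

__all__ = [
    "GEO_ACCESSIONS",
    "expression_difference_scores",
    "hai_outcome",
    "run_flu_recipe",
    "make_synthetic_flu_fixture",
]

#: Provenance of the public vaccine-study data this recipe is designed for.
GEO_ACCESSIONS = ("GSE29614", "GSE29617")

HAI_ASSAY_COUNT = 3


def expression_difference_scores(
    baseline: np.ndarray, day3: np.ndarray
) -> ScaledBlock:
    """Day-3 minus baseline expression, centered and scaled per probeset.

    Probesets with identical values across subjects (zero difference
    variance) cannot be scaled and raise; filter them beforehand.
    """
    baseline = np.asarray(baseline, dtype=float)
    day3 = np.asarray(day3, dtype=float)
    if baseline.shape != day3.shape:
        raise ValueError(
            f"baseline and day-3 matrices differ in shape: "
            f"{baseline.shape} vs {day3.shape}"
        )
    return center_scale(day3 - baseline)


def hai_outcome(titers: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Centered maximal log titer change per subject.

    ``titers`` is a long table with columns ``subject``, ``assay``,
    ``baseline`` and ``day28`` (one row per subject x assay; three assays per
    subject).  Returns ``(outcome, subjects)`` where outcome[i] =
    max over assays of (log day28 - log baseline), centered.  Natural
    logarithms are used; non-positive titers raise.
    """
    required = {"subject", "assay", "baseline", "day28"}
    missing = required - set(titers.columns)
    if missing:
        raise ValueError(f"titer table misses columns {sorted(missing)}")
    vals = titers[["baseline", "day28"]].to_numpy(dtype=float)
    if np.any(vals <= 0):
        raise ValueError("non-positive titer: log transform undefined")
    change = np.log(titers["day28"].to_numpy(dtype=float)) - np.log(
        titers["baseline"].to_numpy(dtype=float)
    )
    per_subject = (
        pd.DataFrame({"subject": titers["subject"], "change": change})
        .groupby("subject", sort=True)["change"]
        .agg(["max", "count"])
    )
    if (per_subject["count"] != HAI_ASSAY_COUNT).any():
        raise ValueError(f"each subject needs exactly {HAI_ASSAY_COUNT} assays")
    outcome = per_subject["max"].to_numpy()
    return outcome - outcome.mean(), per_subject.index.to_numpy()


def run_flu_recipe(
    x: ScaledBlock,
    y_centered: np.ndarray,
    n_components: int = 2,
    alpha: float = 0.99,
    stability: StabilitySettings | None = None,
    options: FitOptions | None = None,
) -> tuple[StabilityResult, "object"]:
    """Full analysis: sparse PCovR with stability-selected lasso.

    ``y_centered`` is the centered (unscaled) outcome vector; internally it is
    wrapped as a single-column block with its root sum of squares recorded so
    the loss normalization stays well defined.
    """
    y = np.asarray(y_centered, dtype=float).ravel()
    norm = np.linalg.norm(y)
    if norm == 0:
        raise ValueError("outcome is identically zero")
    y_block = ScaledBlock(
        values=(y / norm)[:, None],
        column_means=np.zeros(1),
        column_norms=np.array([norm]),
    )
    settings = PenaltySettings(alpha=alpha, n_components=n_components)
    stability = stability or StabilitySettings()
    options = options or FitOptions()
    return run_stability_selection(x, y_block, settings, stability, options)


def make_synthetic_flu_fixture(
    n_subjects: int = 26, n_probesets: int = 2000, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Synthetic stand-in for the vaccine-study inputs (no real data involved).

    Returns (baseline expression, day-3 expression, titer table) with a
    planted two-component structure in the difference scores and an outcome
    correlated with the first component, shaped like the real study
    (26 subjects x ~2000 probesets on the default).
    """
    rng = np.random.default_rng(seed)
    baseline = rng.normal(6.0, 1.0, size=(n_subjects, n_probesets))
    t = rng.standard_normal((n_subjects, 2))
    loadings = np.zeros((n_probesets, 2))
    active = rng.choice(n_probesets, size=max(20, n_probesets // 20), replace=False)
    half = active.size // 2
    loadings[active[:half], 0] = rng.normal(1.0, 0.2, size=half)
    loadings[active[half:], 1] = rng.normal(1.0, 0.2, size=active.size - half)
    diff = t @ loadings.T + rng.normal(0.0, 0.5, size=(n_subjects, n_probesets))
    day3 = baseline + diff
    log_change = 0.8 * t[:, 0] + rng.normal(0.0, 0.3, size=n_subjects)
    rows = []
    for i in range(n_subjects):
        base_titers = rng.uniform(10.0, 160.0, size=HAI_ASSAY_COUNT)
        shifts = log_change[i] + rng.normal(0.0, 0.1, size=HAI_ASSAY_COUNT)
        for a in range(HAI_ASSAY_COUNT):
            rows.append(
                {
                    "subject": f"s{i:02d}",
                    "assay": f"assay{a}",
                    "baseline": base_titers[a],
                    "day28": base_titers[a] * np.exp(shifts[a]),
                }
            )
    return baseline, day3, pd.DataFrame(rows)
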