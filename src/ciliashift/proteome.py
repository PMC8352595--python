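"""Post-quantification proteome processing.

Takes a label-free-quantification (LFQ) protein intensity matrix through the
standard downstream steps: left-shifted normal imputation of missing values,
per-protein Z-score normalization, GO-term substring subsetting (e.g. every
protein annotated with 'cilia'), and scoring of how closely each protein's
stage trajectory follows the group mean.

Matrices are pandas DataFrames with protein ids as the index and one column
per sample; absent measurements are NaN (a reader option maps 0 to NaN for
files that encode missingness as zero).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_lfq_tsv",
    "read_annotations_tsv",
    "impute_missing",
    "z_normalize",
    "go_subset",
    "trajectory_match",
]


def read_lfq_tsv(path: str | Path, zero_is_missing: bool = True) -> pd.DataFrame:
    """Read a protein_id x sample intensity TSV; optionally map 0 to NaN."""
    matrix = pd.read_csv(path, sep="\t", index_col="protein_id")
    if zero_is_missing:
        matrix = matrix.mask(matrix == 0)
    return matrix


def read_annotations_tsv(path: str | Path) -> pd.DataFrame:
    """Read a (protein_id, go_terms) annotation TSV."""
    return pd.read_csv(path, sep="\t")


def impute_missing(
    matrix: pd.DataFrame,
    width: float = 0.3,
    downshift: float = 1.8,
    seed: int | None = None,
) -> pd.DataFrame:
    """Impute missing intensities from a left-shifted normal, column-wise.

    For each sample column, missing (NaN or 0) entries are drawn on the log2
    scale from Normal(mean - downshift * SD, (width * SD)^2), where mean and
    SD are the column's observed log2-intensity statistics, then mapped back
    to the intensity scale.  This mimics the convention that missing values
    arise from low-abundance proteins near the detection limit.  Present
    values are never altered.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    out = matrix.copy().astype(float)
    out = out.mask(out == 0)
    for col in out.columns:
        values = out[col]
        missing = values.isna()
        present = values[~missing]
        if len(present) < 2:
            raise ValueError(
                f"column {col!r} has fewer than 2 observed values; cannot impute"
            )
        if not missing.any():
            continue
        log_present = np.log2(present.to_numpy())
        mu = log_present.mean() - downshift * log_present.std(ddof=1)
        sd = width * log_present.std(ddof=1)
        draws = rng.normal(mu, sd, size=int(missing.sum()))
        out.loc[missing, col] = 2.0**draws
    return out


def z_normalize(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Per-row Z-score: subtract the row mean, divide by the row sample SD.

    Rows with zero variance cannot be scaled; they become all-zero profiles
    and are flagged in the returned boolean Series.
    """
    values = matrix.to_numpy(dtype=float)
    if values.shape[1] < 2:
        raise ValueError("Z-normalization needs at least 2 samples per row")
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    constant = (sd == 0).ravel()
    safe_sd = np.where(sd == 0, 1.0, sd)
    z = (values - mean) / safe_sd
    z[constant] = 0.0
    return (
        pd.DataFrame(z, index=matrix.index, columns=matrix.columns),
        pd.Series(constant, index=matrix.index, name="constant"),
    )


def go_subset(
    matrix: pd.DataFrame, annotations: pd.DataFrame, term: str = "cilia"
) -> pd.DataFrame:
    """Retain proteins whose GO annotation contains ``term`` (case-insensitive).

    The match is a plain substring test on the concatenated GO strings, so
    'cilia' also catches 'ciliary ...' annotations.  Proteins without an
    annotation entry are treated as having no terms and dropped.
    """
    ann = annotations.set_index("protein_id")["go_terms"].astype(str)
    terms = ann.reindex(matrix.index).fillna("")
    keep = terms.str.contains(term, case=False, regex=False)
    return matrix.loc[keep.to_numpy()]


def trajectory_match(zmatrix: pd.DataFrame, r_threshold: float = 0.8) -> pd.DataFrame:
    """Score each protein's Z-profile against the group mean trajectory.

    The group mean trajectory is the per-stage mean of all Z-profiles; each
    protein gets the Pearson correlation of its profile with that mean and a
    label: ``match`` when r >= r_threshold, else ``deviate``.  Proteins with
    constant profiles have undefined correlation and are labelled ``deviate``
    with the ``flagged`` column set.
    """
    if zmatrix.shape[0] < 2 or zmatrix.shape[1] < 3:
        raise ValueError("trajectory matching needs >= 2 proteins and >= 3 stages")
    z = zmatrix.to_numpy(dtype=float)
    mean_traj = z.mean(axis=0)
    zc = z - z.mean(axis=1, keepdims=True)
    mc = mean_traj - mean_traj.mean()
    denom = np.sqrt((zc**2).sum(axis=1) * (mc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (zc * mc).sum(axis=1) / denom, np.nan)
    flagged = np.isnan(r)
    label = np.where(~flagged & (r >= r_threshold), "match", "deviate")
    return pd.DataFrame(
        {"r": r, "label": label, "flagged": flagged}, index=zmatrix.index
    )
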