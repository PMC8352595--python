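"""Polysome-shift translation analysis.

Quantifies how the association of each mRNA with polysomes changes between two
genotypes from fraction-resolved RNA-seq count tables.  For each gene *a* and
sample *N* a length-normalized read density is computed on the TPM scale,

    d(a, N) = 1e6 * (n(a, N) / length(a)) / sum_j (n(j, N) / length(j)),

from which a polysome index

    PI(a) = d(a, poly) / (d(a, poly) + d(a, sub))

gives the proportion of the transcript's density found in the polysomal
fractions.  The polysome shift ratio

    PSR(a) = log2(PI_mut(a) / PI_wt(a))

compares mutant against wild type: negative values mean the transcript is
depleted from polysomes in the mutant.  PI and PSR are computed from
replicate-pooled counts; significance is assessed by an equal-variance
two-sample t-test on the per-replicate PIs.

Count tables use one column per sample named ``<genotype>_<fraction>_rep<k>``
plus ``gene_id`` and ``length`` columns (the schema written by
:mod:`ciliashift.simulate`).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SampleKey",
    "parse_sample_columns",
    "pool_replicates",
    "tpm_density",
    "polysome_index",
    "polysome_shift_ratio",
    "replicate_pi_table",
    "psr_significance",
    "classify_shifted_genes",
    "go_input_filter",
    "expression_filter",
    "run_psr",
    "read_counts_tsv",
    "write_psr_tsv",
]

_SAMPLE_RE = re.compile(r"^(?P<genotype>[^_]+)_(?P<fraction>[^_]+)_rep(?P<rep>\d+)$")

POLY = "poly"
SUB = "sub"
CYTO = "cyto"


@dataclass(frozen=True)
class SampleKey:
    """Metadata parsed from one sample column name."""

    genotype: str
    fraction: str
    replicate: int
    column: str


def parse_sample_columns(table: pd.DataFrame) -> list[SampleKey]:
    """Parse ``<genotype>_<fraction>_rep<k>`` column names into keys.

    Columns that do not match the pattern (e.g. ``gene_id``, ``length``) are
    ignored.  Duplicate sample labels raise ``ValueError``.
    """
    keys = []
    for col in table.columns:
        m = _SAMPLE_RE.match(str(col))
        if m:
            keys.append(
                SampleKey(m["genotype"], m["fraction"], int(m["rep"]), col)
            )
    seen = set()
    for k in keys:
        ident = (k.genotype, k.fraction, k.replicate)
        if ident in seen:
            raise ValueError(f"duplicate sample label: {k.column}")
        seen.add(ident)
    return keys


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Read a gene count table (gene_id, length, sample columns) from TSV."""
    table = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "length"):
        if col not in table.columns:
            raise ValueError(f"count table is missing required column {col!r}")
    if (table["length"] <= 0).any():
        raise ValueError("transcript lengths must be strictly positive")
    return table


def pool_replicates(table: pd.DataFrame, genotype: str, fraction: str) -> pd.Series:
    """Sum replicate read counts for one (genotype, fraction).

    Returns a per-gene Series indexed like ``table`` with name
    ``<genotype>_<fraction>_pooled``.  Raises ``KeyError`` when no sample
    matches.
    """
    cols = [
        k.column
        for k in parse_sample_columns(table)
        if k.genotype == genotype and k.fraction == fraction
    ]
    if not cols:
        raise KeyError(f"no samples for genotype={genotype!r}, fraction={fraction!r}")
    pooled = table[cols].sum(axis=1)
    pooled.name = f"{genotype}_{fraction}_pooled"
    pooled.attrs["pooled_columns"] = cols
    return pooled


def tpm_density(counts, lengths) -> pd.Series:
    """TPM read density: d(a) = 1e6 * (n(a)/L(a)) / sum_j n(j)/L(j).

    The returned column sums to 1e6.  Raises ``ValueError`` on an all-zero
    sample or non-positive lengths.
    """
    counts = pd.Series(np.asarray(counts, dtype=float))
    lengths = np.asarray(lengths, dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("transcript lengths must be strictly positive")
    rate = counts.to_numpy() / lengths
    total = rate.sum()
    if total <= 0:
        raise ValueError("empty sample: all read counts are zero")
    return pd.Series(1e6 * rate / total, index=counts.index, name="tpm")


def polysome_index(d_poly, d_sub) -> pd.Series:
    """PI(a) = d_poly / (d_poly + d_sub); NaN where both densities are 0."""
    d_poly = np.asarray(d_poly, dtype=float)
    d_sub = np.asarray(d_sub, dtype=float)
    if d_poly.shape != d_sub.shape:
        raise ValueError("polysomal and subpolysomal density columns differ in length")
    denom = d_poly + d_sub
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(denom > 0, d_poly / denom, np.nan)
    return pd.Series(pi, name="pi")


def polysome_shift_ratio(pi_mut, pi_wt) -> pd.Series:
    """PSR(a) = log2(PI_mut / PI_wt); NaN where either PI is 0 or undefined."""
    pi_mut = np.asarray(pi_mut, dtype=float)
    pi_wt = np.asarray(pi_wt, dtype=float)
    ok = (pi_mut > 0) & (pi_wt > 0)
    psr = np.full(pi_mut.shape, np.nan)
    psr[ok] = np.log2(pi_mut[ok] / pi_wt[ok])
    return pd.Series(psr, name="psr")


def replicate_pi_table(table: pd.DataFrame, genotype: str) -> pd.DataFrame:
    """Per-replicate polysome indices for one genotype (genes x replicates).

    Each replicate's poly and sub samples are TPM-normalized independently
    before forming the PI.  Replicates are matched by replicate id across the
    poly and sub fractions.
    """
    keys = parse_sample_columns(table)
    poly = {k.replicate: k.column for k in keys if k.genotype == genotype and k.fraction == POLY}
    sub = {k.replicate: k.column for k in keys if k.genotype == genotype and k.fraction == SUB}
    reps = sorted(set(poly) & set(sub))
    if not reps:
        raise KeyError(f"no paired poly/sub replicates for genotype {genotype!r}")
    out = {}
    for r in reps:
        d_p = tpm_density(table[poly[r]], table["length"])
        d_s = tpm_density(table[sub[r]], table["length"])
        out[r] = polysome_index(d_p, d_s)
    return pd.DataFrame(out, index=table.index)


def psr_significance(replicate_pis_mut: pd.DataFrame, replicate_pis_wt: pd.DataFrame) -> pd.Series:
    """Two-sided equal-variance t-test on per-replicate PIs, gene by gene.

    Conventions for degenerate genes:

    * fewer than 2 defined replicate PIs in either genotype -> NaN (untestable);
    * zero pooled variance with equal means -> p = 1;
    * zero pooled variance with unequal means -> p = 0.
    """
    x = np.asarray(replicate_pis_mut, dtype=float)
    y = np.asarray(replicate_pis_wt, dtype=float)
    if x.shape[0] != y.shape[0]:
        raise ValueError("mutant and wild-type PI tables cover different gene sets")
    p = np.full(x.shape[0], np.nan)
    nx = np.sum(~np.isnan(x), axis=1)
    ny = np.sum(~np.isnan(y), axis=1)
    testable = (nx >= 2) & (ny >= 2)
    if not testable.any():
        return pd.Series(p, name="p_value")

    with np.errstate(invalid="ignore"):
        mx = np.nanmean(x, axis=1)
        my = np.nanmean(y, axis=1)
        vx = np.nanvar(x, axis=1, ddof=1)
        vy = np.nanvar(y, axis=1, ddof=1)
    df = nx + ny - 2
    pooled = ((nx - 1) * vx + (ny - 1) * vy) / np.where(df > 0, df, 1)
    se = np.sqrt(pooled * (1.0 / np.where(nx > 0, nx, 1) + 1.0 / np.where(ny > 0, ny, 1)))

    zero_var = testable & (pooled == 0)
    p[zero_var & (mx == my)] = 1.0
    p[zero_var & (mx != my)] = 0.0

    regular = testable & (pooled > 0)
    t = np.zeros(x.shape[0])
    t[regular] = (mx[regular] - my[regular]) / se[regular]
    p[regular] = 2.0 * sps.t.sf(np.abs(t[regular]), df[regular])
    return pd.Series(p, name="p_value")


def classify_shifted_genes(psr_table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Label each gene down / up / unchanged / undefined.

    ``down``: p < alpha and PSR < 0; ``up``: p < alpha and PSR > 0;
    ``undefined``: PSR or p-value not computable; otherwise ``unchanged``.
    """
    out = psr_table.copy()
    psr = out["psr"].to_numpy(dtype=float)
    p = out["p_value"].to_numpy(dtype=float)
    label = np.full(len(out), "unchanged", dtype=object)
    label[np.isnan(psr) | np.isnan(p)] = "undefined"
    sig = ~np.isnan(psr) & ~np.isnan(p) & (p < alpha)
    label[sig & (psr < 0)] = "down"
    label[sig & (psr > 0)] = "up"
    out["class"] = label
    return out


def go_input_filter(
    psr_table: pd.DataFrame, down_fold: float = 0.85, up_fold: float = 1.15
) -> tuple[list, list]:
    """Gene lists for GO enrichment input.

    Down list: PSR <= round(log2(down_fold), 2) (default bound -0.23, i.e. at
    least a 0.85-fold drop in PI).  Up list: PSR >= round(log2(up_fold), 2)
    (default 0.20).  Bounds are inclusive.
    """
    for name, fold in (("down_fold", down_fold), ("up_fold", up_fold)):
        if not (0 < fold < np.inf):
            raise ValueError(f"{name} must be a positive finite fold change")
    down_thr = round(float(np.log2(down_fold)), 2)
    up_thr = round(float(np.log2(up_fold)), 2)
    psr = psr_table["psr"]
    down = psr_table.loc[psr <= down_thr, "gene_id"].tolist()
    up = psr_table.loc[psr >= up_thr, "gene_id"].tolist()
    return down, up


def expression_filter(
    table: pd.DataFrame, mean_tpm: pd.Series, min_mean_tpm: float = 0.5
) -> pd.DataFrame:
    """Keep genes whose mean TPM is strictly above the threshold."""
    keep = np.asarray(mean_tpm, dtype=float) > min_mean_tpm
    return table.loc[keep].reset_index(drop=True)


def run_psr(
    table: pd.DataFrame,
    wt: str = "WT",
    mut: str = "NRS",
    alpha: float = 0.05,
    min_mean_tpm: float | None = None,
    fdr: bool = False,
) -> pd.DataFrame:
    """Full pipeline: pooled PI per genotype, PSR, t-test p-values, classes.

    ``min_mean_tpm`` (when given) drops genes whose mean TPM across all
    samples is not strictly above the threshold before testing.  ``fdr`` adds
    a Benjamini-Hochberg adjusted column and classifies on it instead of the
    raw p-value.
    """
    table = table.reset_index(drop=True)
    keys = parse_sample_columns(table)
    if not keys:
        raise ValueError("no sample columns found (expected <genotype>_<fraction>_rep<k>)")

    density_cols = {
        k.column: tpm_density(table[k.column], table["length"]) for k in keys
    }
    mean_tpm = pd.concat(density_cols, axis=1).mean(axis=1)
    if min_mean_tpm is not None:
        table = expression_filter(table, mean_tpm, min_mean_tpm)
        mean_tpm = mean_tpm[np.asarray(mean_tpm) > min_mean_tpm].reset_index(drop=True)

    pis = {}
    for genotype in (wt, mut):
        d_poly = tpm_density(pool_replicates(table, genotype, POLY), table["length"])
        d_sub = tpm_density(pool_replicates(table, genotype, SUB), table["length"])
        pis[genotype] = polysome_index(d_poly, d_sub)

    psr = polysome_shift_ratio(pis[mut], pis[wt])
    p = psr_significance(replicate_pi_table(table, mut), replicate_pi_table(table, wt))

    result = pd.DataFrame(
        {
            "gene_id": table["gene_id"],
            f"pi_{wt}": pis[wt],
            f"pi_{mut}": pis[mut],
            "psr": psr,
            "p_value": p,
            "mean_tpm": np.asarray(mean_tpm),
        }
    )
    if fdr:
        from statsmodels.stats.multitest import multipletests

        ok = ~result["p_value"].isna()
        q = np.full(len(result), np.nan)
        if ok.any():
            q[ok.to_numpy()] = multipletests(result.loc[ok, "p_value"], method="fdr_bh")[1]
        result["q_value"] = q
        classified = classify_shifted_genes(
            result.rename(columns={"p_value": "_raw_p", "q_value": "p_value"}), alpha
        ).rename(columns={"p_value": "q_value", "_raw_p": "p_value"})
        result = classified[list(result.columns) + ["class"]]
    else:
        result = classify_shifted_genes(result, alpha)
    return result


def write_psr_tsv(result: pd.DataFrame, path: str | Path, summary: dict | None = None) -> None:
    """Write a PSR table as TSV, plus an optional JSON run summary alongside."""
    path = Path(path)
    result.to_csv(path, sep="\t", index=False, float_format="%.6g")
    if summary is not None:
        path.with_suffix(".summary.json").write_text(json.dumps(summary, indent=2))
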