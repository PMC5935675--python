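"""Transcriptional pharmacodynamics on a gene-by-sample count matrix.

Stages: tumor-content QC on the sample sheet, TPM conversion, per-gene
pre/post tests on log2(TPM+1), signature scoring (mean per-gene z-score),
and generic hypergeometric gene-set over-representation with
Benjamini-Hochberg adjustment. The per-gene test is a plain two-sample
t-test; shrinkage-based differential-expression machinery is deliberately
out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from trialcorr.stats import ComparisonResult, paired_t_test, welch_or_student_t

DEFAULT_MIN_TUMOR_FRACTION = 0.20
DEFAULT_SIGNATURE_COVERAGE = 0.50


class QCError(ValueError):
    """All samples failed tumor-content QC."""


def read_gmt(path_or_buffer) -> dict[str, list[str]]:
    """Parse a GMT gene-set file: name <tab> description <tab> genes..."""
    sets: dict[str, list[str]] = {}
    if hasattr(path_or_buffer, "read"):
        lines = path_or_buffer.read().splitlines()
    else:
        with open(path_or_buffer) as fh:
            lines = fh.read().splitlines()
    for line in lines:
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def load_default_signatures() -> dict[str, list[str]]:
    """The two bundled placeholder pathway signatures (editable fixtures)."""
    ref = resources.files("trialcorr.data") / "stat3_signatures.gmt"
    with ref.open() as fh:
        return read_gmt(fh)


def qc_filter(counts: pd.DataFrame, sample_sheet: pd.DataFrame,
              min_tumor_fraction: float = DEFAULT_MIN_TUMOR_FRACTION
              ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Drop samples with tumor_fraction strictly below the threshold.

    Returns (filtered counts, filtered sheet, exclusion log). Samples
    exactly at the threshold are retained. Raises :class:`QCError` if
    nothing survives.
    """
    if "tumor_fraction" not in sample_sheet.columns:
        raise ValueError("sample sheet lacks a tumor_fraction column")
    sheet = sample_sheet.set_index("sample_id", drop=False)
    missing = [c for c in counts.columns if c not in sheet.index]
    if missing:
        raise ValueError(f"samples absent from sheet: {missing}")
    tf = sheet.loc[list(counts.columns), "tumor_fraction"].astype(float)
    keep = tf >= min_tumor_fraction
    excluded = pd.DataFrame({
        "sample_id": tf.index[~keep],
        "tumor_fraction": tf[~keep].to_numpy(),
        "reason": f"tumor_fraction < {min_tumor_fraction}",
    })
    if not keep.any():
        raise QCError("all samples excluded by tumor-content QC")
    kept_ids = list(tf.index[keep])
    return (counts.loc[:, kept_ids],
            sample_sheet[sample_sheet["sample_id"].isin(kept_ids)],
            excluded.reset_index(drop=True))


def to_tpm(counts: pd.DataFrame, lengths_kb: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million: length-normalize, then scale columns to 1e6.

    Columns with zero total get all-NaN TPM and a warning (undefined).
    """
    lengths = lengths_kb.reindex(counts.index)
    if lengths.isna().any():
        raise ValueError("gene lengths missing for some genes")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be positive")
    rate = counts.div(lengths, axis=0)
    denom = rate.sum(axis=0)
    zero = denom == 0
    if zero.any():
        warnings.warn(f"samples with zero counts have undefined TPM: "
                      f"{list(denom.index[zero])}", stacklevel=2)
    denom = denom.replace(0, np.nan)
    return rate.div(denom, axis=1) * 1e6


def _group_columns(sample_sheet: pd.DataFrame, tpm: pd.DataFrame,
                   groups: tuple[str, str]) -> tuple[list[str], list[str]]:
    sheet = sample_sheet.set_index("sample_id")
    cols_a = [c for c in tpm.columns
              if sheet.loc[c, "timepoint"] == groups[0]]
    cols_b = [c for c in tpm.columns
              if sheet.loc[c, "timepoint"] == groups[1]]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need at least 2 samples per group")
    return cols_a, cols_b


def gene_test(tpm: pd.DataFrame, gene: str, sample_sheet: pd.DataFrame,
              groups: tuple[str, str] = ("baseline", "cycle2"),
              pseudocount: float = 1.0,
              paired: bool = False) -> ComparisonResult:
    """Two-sample (or paired) t-test on log2(TPM + pseudocount) for one gene.

    ``estimate`` is mean(group b) - mean(group a) on the log2 scale, so a
    negative value means repression in the second group.
    """
    if gene not in tpm.index:
        raise KeyError(f"gene not in matrix: {gene!r}")
    cols_a, cols_b = _group_columns(sample_sheet, tpm, groups)
    a = np.log2(tpm.loc[gene, cols_a].to_numpy(dtype=float) + pseudocount)
    b = np.log2(tpm.loc[gene, cols_b].to_numpy(dtype=float) + pseudocount)
    if paired:
        res = paired_t_test(b, a)
    else:
        res = welch_or_student_t(b, a)
    return ComparisonResult(statistic=res.statistic, p_value=res.p_value,
                            test_name=res.test_name, n=res.n,
                            estimate=float(b.mean() - a.mean()),
                            extra={"gene": gene})


def all_gene_tests(tpm: pd.DataFrame, sample_sheet: pd.DataFrame,
                   groups: tuple[str, str] = ("baseline", "cycle2"),
                   pseudocount: float = 1.0) -> pd.DataFrame:
    """Vectorized per-gene t-tests; returns gene, log2_diff, t, p columns."""
    cols_a, cols_b = _group_columns(sample_sheet, tpm, groups)
    a = np.log2(tpm[cols_a].to_numpy(dtype=float) + pseudocount)
    b = np.log2(tpm[cols_b].to_numpy(dtype=float) + pseudocount)
    t, p = sps.ttest_ind(b, a, axis=1)
    diff = b.mean(axis=1) - a.mean(axis=1)
    # degenerate rows (zero variance in both groups): no evidence either way
    degen = np.isnan(t)
    t = np.where(degen, 0.0, t)
    p = np.where(degen, 1.0, p)
    return pd.DataFrame({"gene": tpm.index, "log2_diff": diff,
                         "t": t, "p": p}).set_index("gene")


@dataclass(frozen=True)
class SignatureScores:
    """Per-sample pathway score: mean per-gene z of log2(TPM+1)."""

    signature_name: str
    scores: pd.Series | None
    coverage: float
    genes_used: tuple[str, ...]

    @property
    def defined(self) -> bool:
        return self.scores is not None


def signature_score(tpm: pd.DataFrame, signature: list[str],
                    name: str = "signature",
                    pseudocount: float = 1.0,
                    min_coverage: float = DEFAULT_SIGNATURE_COVERAGE
                    ) -> SignatureScores:
    """Score each sample as the mean standardized log-expression of the set.

    Genes constant across samples contribute z = 0 (flagged via
    ``genes_used`` still including them). If fewer than ``min_coverage`` of
    the signature genes are present the score is undefined.
    """
    present = [g for g in signature if g in tpm.index]
    coverage = len(present) / len(signature) if signature else 0.0
    if coverage < min_coverage:
        return SignatureScores(signature_name=name, scores=None,
                               coverage=coverage, genes_used=())
    logx = np.log2(tpm.loc[present].to_numpy(dtype=float) + pseudocount)
    mu = logx.mean(axis=1, keepdims=True)
    sd = logx.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (logx - mu) / sd, 0.0)
    scores = pd.Series(z.mean(axis=0), index=tpm.columns, name=name)
    return SignatureScores(signature_name=name, scores=scores,
                           coverage=coverage, genes_used=tuple(present))


def signature_test(scores: SignatureScores, sample_sheet: pd.DataFrame,
                   groups: tuple[str, str] = ("baseline", "cycle2"),
                   paired: bool = False) -> ComparisonResult:
    """Compare signature scores between timepoints (t-test by default)."""
    if not scores.defined:
        raise ValueError(f"signature {scores.signature_name!r} undefined "
                         f"(coverage {scores.coverage:.0%})")
    sheet = sample_sheet.set_index("sample_id")
    s = scores.scores
    a = s[[c for c in s.index if sheet.loc[c, "timepoint"] == groups[0]]]
    b = s[[c for c in s.index if sheet.loc[c, "timepoint"] == groups[1]]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 samples per group")
    res = paired_t_test(b.to_numpy(), a.to_numpy()) if paired \
        else welch_or_student_t(b.to_numpy(), a.to_numpy())
    return ComparisonResult(statistic=res.statistic, p_value=res.p_value,
                            test_name=res.test_name, n=res.n,
                            estimate=float(b.mean() - a.mean()),
                            extra={"signature": scores.signature_name})


def gene_set_enrichment(de_genes: list[str], universe: list[str],
                        sets: dict[str, list[str]]) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per set, BH-adjusted.

    ``de_genes`` must be a subset of ``universe``; set members outside the
    universe are ignored for the overlap arithmetic.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    de = set(de_genes)
    if not de <= uni:
        raise ValueError("de_genes must be a subset of the universe")
    if not sets:
        raise ValueError("no gene sets supplied")
    rows = []
    n_uni, n_de = len(uni), len(de)
    for name, members in sets.items():
        m = set(members) & uni
        k = len(m & de)
        # P(overlap >= k) for Hypergeom(N=n_uni, K=len(m), n=n_de)
        p = float(sps.hypergeom.sf(k - 1, n_uni, len(m), n_de)) if m else 1.0
        rows.append({"set": name, "set_size": len(m), "overlap": k, "p": p})
    out = pd.DataFrame(rows).set_index("set")
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    return out.sort_values("p")
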