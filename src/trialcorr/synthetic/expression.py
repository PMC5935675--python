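"""Synthetic pre/post count matrices with a planted pathway contrast.

Counts are negative-binomial around lognormal per-gene baselines, with
per-sample library-size factors varied +/-30%. Genes in the two pathway
signatures shift post-treatment by ``target_effect`` (log2 fold change,
negative = suppression); genes in ``repressed_genes`` shift by the opposite
sign. Gene lengths (kb) are drawn uniformly unless supplied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from trialcorr.expression import load_default_signatures


def _default_signatures() -> tuple[list[str], list[str]]:
    sigs = load_default_signatures()
    names = list(sigs)
    return list(sigs[names[0]]), list(sigs[names[1]])


@dataclass(frozen=True)
class ExpressionSpec:
    n_genes: int = 500
    n_pre: int = 11
    n_post: int = 4
    signature_genes: tuple[list[str], list[str]] | None = None
    repressed_genes: tuple[str, ...] = ("LCK",)
    target_effect: float = -1.0     # log2 FC applied to signature genes post
    dispersion: float = 0.05        # NB dispersion (1/size)
    gene_lengths: np.ndarray | None = None   # kb, per gene
    base_log_mean: float = 5.0      # log of mean counts
    base_log_sd: float = 1.0
    library_cv: float = 0.3         # library factors ~ U(1-cv, 1+cv)
    tumor_fraction_range: tuple[float, float] = (0.25, 0.95)
    seed: int = 0

    def __post_init__(self):
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        sigs = self.signature_genes or _default_signatures()
        n_named = len(set(sigs[0]) | set(sigs[1]) | set(self.repressed_genes))
        if self.n_genes < n_named:
            raise ValueError("n_genes smaller than the named gene lists")
        if self.n_pre < 2 or self.n_post < 2:
            raise ValueError("need at least 2 samples per arm")

    def resolved_signatures(self) -> tuple[list[str], list[str]]:
        return self.signature_genes or _default_signatures()


def generate_expression(spec: ExpressionSpec
                        ) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Returns (counts genes x samples, gene_lengths_kb, sample_sheet).

    Sample sheet columns: sample_id, patient_id, timepoint
    (baseline/cycle2), tumor_fraction.
    """
    seqs = np.random.SeedSequence(spec.seed).spawn(4)
    rng_gene, rng_lib, rng_count, rng_sheet = (
        np.random.Generator(np.random.PCG64(s)) for s in seqs)

    sig_a, sig_b = spec.resolved_signatures()
    named = list(dict.fromkeys([*sig_a, *sig_b, *spec.repressed_genes]))
    genes = named + [f"G{i:05d}" for i in range(spec.n_genes - len(named))]

    base_mu = np.exp(rng_gene.normal(spec.base_log_mean, spec.base_log_sd,
                                     spec.n_genes))
    if spec.gene_lengths is not None:
        lengths = np.asarray(spec.gene_lengths, dtype=float)
        if lengths.shape != (spec.n_genes,) or (lengths <= 0).any():
            raise ValueError("gene_lengths must be positive, one per gene")
    else:
        lengths = rng_gene.uniform(0.5, 5.0, spec.n_genes)

    n_samples = spec.n_pre + spec.n_post
    timepoint = np.array(["baseline"] * spec.n_pre + ["cycle2"] * spec.n_post)
    lib = rng_lib.uniform(1.0 - spec.library_cv, 1.0 + spec.library_cv,
                          n_samples)

    lfc = np.zeros(spec.n_genes)
    sig_set = set(sig_a) | set(sig_b)
    for i, g in enumerate(genes):
        if g in sig_set:
            lfc[i] = spec.target_effect
        elif g in spec.repressed_genes:
            lfc[i] = -spec.target_effect

    post = timepoint == "cycle2"
    mu = base_mu[:, None] * lib[None, :]
    mu = mu * np.where(post[None, :], 2.0 ** lfc[:, None], 1.0)

    size = 1.0 / spec.dispersion
    p = size / (size + mu)
    counts = rng_count.negative_binomial(size, p)

    sample_ids = [f"S{i + 1:03d}" for i in range(n_samples)]
    tf_lo, tf_hi = spec.tumor_fraction_range
    sheet = pd.DataFrame({
        "sample_id": sample_ids,
        "patient_id": [f"PT{i + 1:03d}" for i in range(n_samples)],
        "timepoint": timepoint,
        "tumor_fraction": rng_sheet.uniform(tf_lo, tf_hi, n_samples),
    })
    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene"),
                             columns=sample_ids)
    lengths_s = pd.Series(lengths, index=counts_df.index, name="length_kb")
    return counts_df, lengths_s, sheet
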