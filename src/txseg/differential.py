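"""Differential segment usage and differential splicing tests.

Differential segment usage adopts the differential-exon-usage design with
segments as the counting units: per gene and segment, counts for (this
segment, rest of gene) across samples are modelled with a negative
binomial GLM.  The full model contains sample effects, a segment-bin
effect and a condition x bin interaction; the null model drops the
interaction, and the two are compared with a 1-df likelihood-ratio
chi-square.  Per gene, the minimum segment p-value is Sidak-corrected for
the number of segments tested, and gene-level FDR is controlled with
Benjamini-Hochberg across genes.  Dispersion is a per-gene common value
estimated by maximum likelihood on the gene's count table (the counting
statistic, not the testing machinery, is the point here; the exporter
below provides full fidelity via the external exon-usage tool).

Differential splicing fits, per event, an ordinary linear model of PSI on
condition and t-tests the condition coefficient, with BH across events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .library import Segment
from .quantification import PsiTable, SegmentCountMatrix

__all__ = [
    "DesignSpec",
    "DiffResult",
    "test_differential_segment_usage",
    "test_differential_psi",
    "export_for_dexseq",
    "size_factors",
]


@dataclass
class DesignSpec:
    """Two-level condition factor over samples (optional covariates are
    accepted but not modelled by the built-in tests)."""

    sample_ids: List[str]
    condition: List[str]
    covariates: Optional[pd.DataFrame] = None

    def __post_init__(self):
        if len(self.sample_ids) != len(self.condition):
            raise ValueError("sample_ids and condition differ in length")
        levels = sorted(set(self.condition))
        if len(levels) != 2:
            raise ValueError(
                f"need exactly two condition levels, got {levels}"
            )
        counts = {lv: self.condition.count(lv) for lv in levels}
        if min(counts.values()) < 2:
            raise ValueError("need >=2 samples per condition")
        self.levels = levels

    def indicator(self) -> np.ndarray:
        return np.array(
            [1.0 if c == self.levels[1] else 0.0 for c in self.condition]
        )


@dataclass
class DiffResult:
    segment_table: pd.DataFrame  # gene_id, seg_id, lfc, pvalue
    gene_table: pd.DataFrame  # gene_id, pvalue, qvalue
    skipped_genes: List[str] = field(default_factory=list)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library-size factors."""
    logs = np.log(counts.replace(0, np.nan))
    ref = logs.mean(axis=1)
    ratios = logs.sub(ref, axis=0)
    sf = np.exp(ratios.median(axis=0, skipna=True))
    sf = sf.fillna(1.0)
    if (sf <= 0).any() or sf.isna().any():
        sf[(sf <= 0) | sf.isna()] = 1.0
    return sf


def _gene_dispersion(y: np.ndarray, mu: np.ndarray, df: int) -> float:
    """Common NB dispersion matching the Pearson chi-square to its
    residual degrees of freedom (guards against the small-sample downward
    bias of plain MLE, which would inflate the likelihood-ratio test)."""
    y = np.asarray(y, dtype=float)
    mu = np.clip(np.asarray(mu, dtype=float), 1e-8, None)
    df = max(df, 1)

    def x2(a: float) -> float:
        return float(np.sum((y - mu) ** 2 / (mu + a * mu * mu)))

    if x2(1e-8) <= df:
        return 1e-8
    lo, hi = 1e-8, 10.0
    if x2(hi) > df:
        return hi
    for _ in range(60):
        mid = np.sqrt(lo * hi)
        if x2(mid) > df:
            lo = mid
        else:
            hi = mid
    return float(np.sqrt(lo * hi))


def _fit_glm(y, X, alpha):
    fam = sm.families.NegativeBinomial(alpha=max(alpha, 1e-8))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=fam)
        return model.fit(maxiter=100, tol=1e-8)


def test_differential_segment_usage(
    scm: SegmentCountMatrix,
    segments: Sequence[Segment],
    design: DesignSpec,
) -> DiffResult:
    """Per-segment NB GLM likelihood-ratio test, gene-level FDR control."""
    counts = scm.counts[design.sample_ids]
    gene_of = {s.seg_id: s.gene_id for s in segments}
    genes: Dict[str, List[str]] = {}
    for seg_id in counts.index:
        if seg_id in gene_of:
            genes.setdefault(gene_of[seg_id], []).append(seg_id)

    cond = design.indicator()
    n = len(design.sample_ids)
    seg_rows = []
    gene_rows = []
    skipped: List[str] = []

    for gene_id, seg_ids in sorted(genes.items()):
        sub = counts.loc[seg_ids]
        if len(seg_ids) < 2 or sub.values.sum() == 0:
            skipped.append(gene_id)
            continue
        gene_total = sub.sum(axis=0).values.astype(float)
        pvals = []
        for seg_id in seg_ids:
            this = sub.loc[seg_id].values.astype(float)
            other = gene_total - this
            # observations: (sample x bin) stacked, bin 1 = this segment
            y = np.concatenate([this, other])
            bin_ind = np.concatenate([np.ones(n), np.zeros(n)])
            sample_ind = np.tile(np.arange(n), 2)
            X_cols = [np.ones(2 * n)]
            for s in range(1, n):
                X_cols.append((sample_ind == s).astype(float))
            X_cols.append(bin_ind)
            X_null = np.column_stack(X_cols)
            X_full = np.column_stack(
                X_cols + [bin_ind * np.tile(cond, 2)]
            )
            try:
                fit0 = _fit_glm(y, X_null, 1e-6)
                alpha = _gene_dispersion(
                    y, fit0.mu, 2 * n - X_null.shape[1]
                )
                fit_null = _fit_glm(y, X_null, alpha)
                fit_full = _fit_glm(y, X_full, alpha)
                lr = 2.0 * (fit_full.llf - fit_null.llf)
                lr = max(lr, 0.0)
                p = float(stats.chi2.sf(lr, df=1))
                lfc = float(fit_full.params[-1]) / np.log(2)
            except Exception:
                p, lfc = 1.0, 0.0
            pvals.append(p)
            seg_rows.append((gene_id, seg_id, lfc, p))
        m = len(pvals)
        p_min = min(pvals)
        # Sidak-corrected minimum p as the gene-level p-value
        p_gene = float(1.0 - (1.0 - p_min) ** m) if p_min < 1 else 1.0
        gene_rows.append((gene_id, p_gene))

    gene_table = pd.DataFrame(gene_rows, columns=["gene_id", "pvalue"])
    if len(gene_table):
        gene_table["qvalue"] = multipletests(
            gene_table["pvalue"].values, method="fdr_bh"
        )[1]
    else:
        gene_table["qvalue"] = []
    segment_table = pd.DataFrame(
        seg_rows, columns=["gene_id", "seg_id", "log2_fold_usage", "pvalue"]
    )
    return DiffResult(segment_table, gene_table, skipped)


def test_differential_psi(
    psi: PsiTable, design: DesignSpec
) -> pd.DataFrame:
    """Linear model of PSI on condition per event; BH across events.

    Returns a frame with columns event_id, delta_psi, pvalue, qvalue,
    degenerate (True where PSI was constant or insufficient).
    """
    table = psi.psi[design.sample_ids]
    cond = design.indicator()
    rows = []
    for event_id, row in table.iterrows():
        vals = row.values.astype(float)
        ok = ~np.isnan(vals)
        y = vals[ok]
        x = cond[ok]
        n0 = int((x == 0).sum())
        n1 = int((x == 1).sum())
        if n0 < 2 or n1 < 2:
            rows.append((event_id, np.nan, np.nan, True))
            continue
        delta = float(y[x == 1].mean() - y[x == 0].mean())
        if np.allclose(y, y[0]):
            rows.append((event_id, 0.0, 1.0, True))
            continue
        X = sm.add_constant(x)
        fit = sm.OLS(y, X).fit()
        if fit.df_resid <= 0 or not np.isfinite(fit.bse[1]) or fit.bse[1] == 0:
            rows.append((event_id, delta, 1.0, True))
            continue
        rows.append((event_id, delta, float(fit.pvalues[1]), False))
    out = pd.DataFrame(
        rows, columns=["event_id", "delta_psi", "pvalue", "degenerate"]
    )
    mask = out["pvalue"].notna()
    out["qvalue"] = np.nan
    if mask.any():
        out.loc[mask, "qvalue"] = multipletests(
            out.loc[mask, "pvalue"].values, method="fdr_bh"
        )[1]
    return out


def export_for_dexseq(
    scm: SegmentCountMatrix, segments: Sequence[Segment], out_dir
) -> Tuple[str, List[str]]:
    """Flattened exonic-part-style GFF plus one count file per sample.

    Feature ids are ``<gene_id>:<seg_id>`` in both the GFF and the count
    files, so the two can be fed to the external differential-exon-usage
    workflow unchanged.
    """
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gff_path = out_dir / "segments.flattened.gff"

    by_gene: Dict[str, List[Segment]] = {}
    for seg in segments:
        by_gene.setdefault(seg.gene_id, []).append(seg)

    def extent(s: Segment) -> Tuple[int, int]:
        if s.genomic_spans:
            return (
                min(l for _b, l, _r in s.genomic_spans),
                max(r for _b, _l, r in s.genomic_spans),
            )
        return min(s.loc, s.end), max(s.loc, s.end)

    with open(gff_path, "w") as fh:
        for gene_id in sorted(by_gene):
            segs = by_gene[gene_id]
            lo = min(extent(s)[0] for s in segs)
            hi = max(extent(s)[1] for s in segs)
            chrom = segs[0].chrom
            strand = segs[0].strand
            fh.write(
                f"{chrom}\ttxseg\taggregate_gene\t{lo + 1}\t{hi}\t.\t"
                f"{strand}\t.\tgene_id \"{gene_id}\"\n"
            )
            for i, seg in enumerate(
                sorted(segs, key=lambda s: s.seg_id), start=1
            ):
                slo, shi = extent(seg)
                fh.write(
                    f"{chrom}\ttxseg\texonic_part\t{slo + 1}\t{shi}\t.\t"
                    f"{strand}\t.\tgene_id \"{gene_id}\"; "
                    f"exonic_part_number \"{i:03d}\"; "
                    f"segment_id \"{seg.seg_id}\"\n"
                )

    feature_id = {
        s.seg_id: f"{s.gene_id}:{s.seg_id}" for s in segments
    }
    count_files = []
    for sample in scm.sample_ids:
        path = out_dir / f"counts.{sample}.txt"
        with open(path, "w") as fh:
            for seg_id in scm.counts.index:
                if seg_id in feature_id:
                    fh.write(
                        f"{feature_id[seg_id]}\t"
                        f"{int(scm.counts.loc[seg_id, sample])}\n"
                    )
        count_files.append(str(path))
    return str(gff_path), count_files
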