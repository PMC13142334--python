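"""Gene-panel scoring, score-marker correlation and promoter motif analysis.

The *barrier score* summarises a panel of genes reported to antagonise
myogenic conversion (ID/TGFB/TWIST/ZEB/SNAI/HES/HEY/NOTCH/WNT5A family
members); the *inflammation score* does the same for inflammatory
cytokines and receptors.  A sample's score is the mean across-sample
z-score of log2 expression over the panel members present — the simplest
reproducible module score (a mean-log variant is available by flag).

Promoter analysis extracts strand-oriented windows spanning 2000 bp
upstream to 200 bp downstream of each TSS (0-based half-open genomic
coordinates; 2200 bp for interior genes), scans consensus motifs — by
default the KLF-family CACCC element and the ETS-family GGAA core — on
both strands with overlaps allowed, and tests foreground-vs-background
promoter enrichment with a one-sided hypergeometric test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .statistics import bh_adjust

__all__ = [
    "GenePanel", "BARRIER_PANEL", "INFLAMMATION_PANEL", "GeneSetScoreResult",
    "PromoterWindow", "MotifEnrichmentResult", "gene_set_score",
    "score_marker_correlation", "extract_promoter_windows", "scan_motifs",
    "motif_enrichment", "reverse_complement", "count_motif", "read_tss_table",
    "DEFAULT_MOTIFS",
]

DEFAULT_MOTIFS: tuple[str, ...] = ("CACCC", "GGAA")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenePanel:
    """A named gene set used for per-sample scoring."""

    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("panel must be non-empty")
        object.__setattr__(self, "members", tuple(self.members))


#: Genes reported to act as barriers to myogenic transdifferentiation
#: (MyoD repression, EMT programs, TGF-beta / Notch progenitor maintenance).
BARRIER_PANEL = GenePanel("barrier", (
    "ID1", "ID2", "ID3", "TGFB1", "TGFB2", "TGFBR1", "TWIST1", "TWIST2",
    "ZEB1", "SNAI1", "SNAI2", "HES1", "HEY1", "NOTCH1", "WNT5A"))

#: Default inflammatory cytokine/receptor panel.  The membership is a
#: user-editable convention, not an authoritative signature; swap in your
#: own panel for real analyses.
INFLAMMATION_PANEL = GenePanel("inflammation", (
    "IL1A", "IL1B", "IL24", "IL32", "CSF2", "CSF3", "CXCL8", "NFKBIA",
    "NFKB2", "STAP2", "TNFRSF21", "TNFRSF19", "STAT3", "NFKB1", "IFI6"))


@dataclass
class GeneSetScoreResult:
    """Per-sample panel score with bookkeeping of the genes used."""

    scores: pd.Series
    used: list[str]
    missing: list[str]
    dropped_degenerate: list[str]


def gene_set_score(matrix: pd.DataFrame, panel: GenePanel,
                   log_transformed: bool = False,
                   method: str = "zscore") -> GeneSetScoreResult:
    """Score each sample for a gene panel.

    ``method='zscore'`` (default): per panel gene, z-score the log2
    expression across samples; the score is the mean z over the panel
    members present.  Genes with zero across-sample variance are dropped
    with a warning.  ``method='mean_log'``: mean log2 expression instead.

    Raises on fewer than 2 samples (z undefined) and when no panel member
    is present in the matrix.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples to score")
    present = [g for g in panel.members if g in matrix.index]
    missing = [g for g in panel.members if g not in matrix.index]
    if not present:
        raise ValueError(f"no members of panel {panel.name!r} in the matrix")

    sub = matrix.loc[present].astype(float)
    log2 = sub if log_transformed else np.log2(sub + 1.0)

    if method == "mean_log":
        return GeneSetScoreResult(scores=log2.mean(axis=0), used=present,
                                  missing=missing, dropped_degenerate=[])
    if method != "zscore":
        raise ValueError("method must be 'zscore' or 'mean_log'")

    sd = log2.std(axis=1, ddof=1)
    degenerate = sd[sd == 0].index.tolist()
    if degenerate:
        warnings.warn(
            f"{len(degenerate)} panel gene(s) with zero variance dropped: "
            f"{degenerate}", UserWarning, stacklevel=2)
    kept = sd[sd > 0].index
    if len(kept) == 0:
        scores = pd.Series(0.0, index=matrix.columns)
        return GeneSetScoreResult(scores=scores, used=[], missing=missing,
                                  dropped_degenerate=degenerate)
    z = log2.loc[kept].sub(log2.loc[kept].mean(axis=1), axis=0).div(
        sd.loc[kept], axis=0)
    return GeneSetScoreResult(scores=z.mean(axis=0), used=list(kept),
                              missing=missing, dropped_degenerate=degenerate)


def score_marker_correlation(scores: pd.Series, matrix: pd.DataFrame,
                             markers: list[str],
                             method: str = "pearson") -> pd.DataFrame:
    """Correlate a per-sample score with each marker's expression.

    Returns a DataFrame indexed by marker with columns ``r``, ``p`` and
    BH-adjusted ``q``.  Markers absent from the matrix are listed with NaN
    and excluded from the adjustment.
    """
    rows = []
    for m in markers:
        if m not in matrix.index:
            rows.append((m, np.nan, np.nan))
            continue
        x = matrix.loc[m].astype(float).values
        y = scores.reindex(matrix.columns).values
        if method == "pearson":
            r, p = stats.pearsonr(y, x)
        elif method == "spearman":
            r, p = stats.spearmanr(y, x)
        else:
            raise ValueError("method must be 'pearson' or 'spearman'")
        rows.append((m, float(r), float(p)))
    df = pd.DataFrame(rows, columns=["marker", "r", "p"]).set_index("marker")
    ok = df["p"].notna()
    df["q"] = np.nan
    if ok.any():
        df.loc[ok, "q"] = bh_adjust(df.loc[ok, "p"].values)
    return df


# ----------------------------------------------------------------------
@dataclass
class PromoterWindow:
    """A strand-oriented promoter window around a TSS.

    Coordinates are 0-based half-open on the + strand of ``chromosome``;
    ``sequence`` is read 5'->3' on the gene's own strand (reverse
    complemented for - strand genes).  ``truncated`` marks windows clipped
    at a contig edge (length < upstream + downstream).
    """

    gene: str
    chromosome: str
    strand: str
    start: int
    end: int
    sequence: str
    truncated: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class MotifEnrichmentResult:
    """Foreground-vs-background promoter enrichment of one motif."""

    motif: str
    foreground_hits: int     # promoters containing >= 1 occurrence
    background_hits: int
    n_foreground: int
    n_background: int
    enrichment_ratio: float  # per-kb occurrence-rate ratio
    p_value: float


def read_tss_table(path) -> pd.DataFrame:
    """Read a TSS table: BED6 or 4-column (gene, chrom, tss, strand).

    For BED6 the TSS is ``start`` on the + strand and ``end - 1`` on the -
    strand (BED intervals are 0-based half-open).
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] >= 6:
        bed = df.iloc[:, :6]
        bed.columns = ["chrom", "start", "end", "gene", "score", "strand"]
        tss = np.where(bed["strand"] == "+", bed["start"], bed["end"] - 1)
        return pd.DataFrame({"gene": bed["gene"], "chrom": bed["chrom"],
                             "tss": tss, "strand": bed["strand"]})
    if df.shape[1] == 4:
        df.columns = ["gene", "chrom", "tss", "strand"]
        return df
    raise ValueError("TSS table must be BED6 or 4 columns "
                     "(gene, chrom, tss, strand)")


def extract_promoter_windows(tss_table: pd.DataFrame, genome,
                             genes: list[str] | None = None,
                             upstream: int = 2000,
                             downstream: int = 200
                             ) -> tuple[list[PromoterWindow], list[str]]:
    """Extract promoter windows around annotated TSSs.

    ``genome`` is a ``pyfaidx.Fasta`` (or any mapping of contig name to
    string-like sequence).  For a + strand gene the genomic window is
    ``[tss - upstream, tss + downstream)``; for a - strand gene it is
    ``[tss - downstream, tss + upstream)`` and the sequence is reverse
    complemented, so the returned sequence always runs from -upstream to
    +downstream in the gene's reading direction (coordinates 0-based
    half-open throughout).  Windows hitting a contig edge are truncated
    and flagged.  Returns ``(windows, skipped_genes)`` where skipped genes
    were requested but absent from the table.
    """
    table = tss_table.set_index("gene") if "gene" in tss_table.columns else tss_table
    wanted = list(table.index) if genes is None else genes
    windows: list[PromoterWindow] = []
    skipped: list[str] = []
    for gene in wanted:
        if gene not in table.index:
            skipped.append(gene)
            continue
        row = table.loc[gene]
        chrom, tss, strand = str(row["chrom"]), int(row["tss"]), str(row["strand"])
        contig = genome[chrom]
        clen = len(contig)
        if strand == "+":
            start, end = tss - upstream, tss + downstream
        elif strand == "-":
            start, end = tss - downstream, tss + upstream
        else:
            raise ValueError(f"invalid strand {strand!r} for gene {gene}")
        truncated = start < 0 or end > clen
        start_c, end_c = max(0, start), min(clen, end)
        seq = str(contig[start_c:end_c]).upper()
        if strand == "-":
            seq = reverse_complement(seq)
        windows.append(PromoterWindow(gene=gene, chromosome=chrom,
                                      strand=strand, start=start_c, end=end_c,
                                      sequence=seq, truncated=truncated))
    return windows, skipped


def count_motif(sequence: str, motif: str,
                both_strands: bool = True) -> int:
    """Count exact occurrences of a consensus motif, overlaps allowed.

    With ``both_strands`` the reverse complement is also counted (unless
    the motif is its own reverse complement).
    """
    seq = sequence.upper()
    patterns = [motif.upper()]
    if both_strands:
        rc = reverse_complement(motif.upper())
        if rc != motif.upper():
            patterns.append(rc)
    total = 0
    for pat in patterns:
        start = 0
        while True:
            i = seq.find(pat, start)
            if i < 0:
                break
            total += 1
            start = i + 1
    return total


def scan_motifs(windows: list[PromoterWindow] | list[str],
                motifs: tuple[str, ...] = DEFAULT_MOTIFS,
                both_strands: bool = True) -> pd.DataFrame:
    """Per-window occurrence counts for each consensus motif."""
    seqs, names = [], []
    for i, w in enumerate(windows):
        if isinstance(w, PromoterWindow):
            seqs.append(w.sequence)
            names.append(w.gene)
        else:
            seqs.append(str(w))
            names.append(f"seq{i}")
    data = {m: [count_motif(s, m, both_strands) for s in seqs] for m in motifs}
    return pd.DataFrame(data, index=names)


def motif_enrichment(foreground: list[PromoterWindow] | list[str],
                     background: list[PromoterWindow] | list[str],
                     motif: str,
                     both_strands: bool = True) -> MotifEnrichmentResult:
    """One-sided hypergeometric enrichment of a motif in foreground promoters.

    A promoter "hits" when it contains at least one occurrence.  The test
    draws the foreground from the pooled foreground+background universe;
    the per-kb occurrence-rate ratio is reported alongside the p-value.
    """
    if len(foreground) == 0:
        raise ValueError("empty foreground promoter set")
    if len(background) == 0:
        raise ValueError("empty background promoter set")
    fg = scan_motifs(foreground, motifs=(motif,), both_strands=both_strands)[motif]
    bg = scan_motifs(background, motifs=(motif,), both_strands=both_strands)[motif]

    def _total_kb(ws) -> float:
        n = 0
        for w in ws:
            n += len(w.sequence) if isinstance(w, PromoterWindow) else len(str(w))
        return n / 1000.0

    k = int((fg > 0).sum())
    b = int((bg > 0).sum())
    M = len(foreground) + len(background)
    K = k + b                     # hit promoters in the universe
    N = len(foreground)
    p = float(stats.hypergeom.sf(k - 1, M, K, N)) if k > 0 else 1.0
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    fg_rate = fg.sum() / max(_total_kb(foreground), 1e-12)
    bg_rate = bg.sum() / max(_total_kb(background), 1e-12)
    ratio = float(fg_rate / bg_rate) if bg_rate > 0 else np.inf
    return MotifEnrichmentResult(
        motif=motif, foreground_hits=k, background_hits=b,
        n_foreground=len(foreground), n_background=len(background),
        enrichment_ratio=ratio, p_value=p)
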