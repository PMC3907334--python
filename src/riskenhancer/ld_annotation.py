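"""From GWAS index SNPs to annotated, classified risk-locus variants.

The post-GWAS annotation stage: for each index SNP, scan a
window (1 Mb total, read as index +/- 500 kb) of a phased panel per
reporting population for proxies with r^2 above a cutoff (0.5 by default),
intersect the surviving variants with chromatin biofeature tracks, classify
them into putative functional categories, merge index SNPs into loci, and
cluster the SNP x biofeature membership matrix.

Functional classes follow a fixed precedence so every SNP lands in exactly
one category: coding_exon > mir_utr (a microRNA target site inside a 5'/3'
UTR) > promoter (strand-aware -1000 bp to +100 bp around a TSS) > enhancer
(any chromatin biofeature membership) > unclassified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .intervals import IntervalTrack, TrackSet
from .panel import HaplotypePanel, MonomorphicVariantError, r2_from_columns

logger = logging.getLogger(__name__)

FUNCTIONAL_CLASSES = ("coding_exon", "mir_utr", "promoter", "enhancer", "unclassified")
PROMOTER_UPSTREAM = 1000
PROMOTER_DOWNSTREAM = 100


@dataclass(frozen=True)
class Variant:
    id: str
    chrom: str
    pos: int            # 1-based
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("positions are 1-based")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")

    @property
    def pos0(self) -> int:
        return self.pos - 1


@dataclass(frozen=True)
class IndexSNP:
    variant: Variant
    populations: tuple[str, ...]
    genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.populations:
            raise ValueError("an index SNP reports in at least one population")


@dataclass(frozen=True)
class CorrelatedSNP:
    index_id: str
    variant: Variant
    r2: dict[str, float]
    tier: str | None = None

    def __post_init__(self) -> None:
        for pop, v in self.r2.items():
            if not 0.0 <= v <= 1.0 + 1e-12:
                raise ValueError(f"r2 out of [0,1] for {pop}: {v}")


@dataclass(frozen=True)
class AnnotatedSNP:
    snp: CorrelatedSNP
    memberships: frozenset[str]
    functional_class: str = "unclassified"

    @property
    def variant(self) -> Variant:
        return self.snp.variant


@dataclass(frozen=True)
class Locus:
    number: int
    index_snps: tuple[str, ...]
    correlated: tuple[str, ...]
    genes: tuple[str, ...] = ()


def _variant_from_row(row) -> Variant:
    return Variant(str(row.id), str(row.chrom), int(row.pos), str(row.ref), str(row.alt))


def find_correlated_snps(
    panels: dict[str, HaplotypePanel],
    index: IndexSNP,
    window: int = 1_000_000,
    r2_min: float = 0.5,
) -> list[CorrelatedSNP]:
    """All variants within +/- window/2 of the index with r^2 >= r2_min in at
    least one reporting population.  The index SNP itself is always included.

    Monomorphic or otherwise LD-undefined variants are skipped with a logged
    warning rather than aborting the scan; output order (by position, then
    id) is invariant to input variant order.
    """
    half = window // 2
    for pop in index.populations:
        if pop not in panels:
            raise KeyError(f"no panel for reporting population {pop!r}")
        if index.variant.id not in panels[pop]:
            raise KeyError(
                f"index SNP {index.variant.id!r} absent from panel {pop!r}")

    r2_by_variant: dict[str, dict[str, float]] = {}
    variant_rows: dict[str, Variant] = {}
    for pop in index.populations:
        panel = panels[pop]
        idx_col = panel.column(index.variant.id)
        vt = panel.variants
        in_window = vt[(vt["chrom"] == index.variant.chrom)
                       & (vt["pos"] >= index.variant.pos - half)
                       & (vt["pos"] <= index.variant.pos + half)]
        for row in in_window.itertuples():
            try:
                r2 = (1.0 if row.id == index.variant.id
                      else r2_from_columns(idx_col, panel.column(row.id)))
            except MonomorphicVariantError:
                logger.warning("skipping monomorphic variant %s in %s", row.id, pop)
                continue
            r2_by_variant.setdefault(row.id, {})[pop] = r2
            variant_rows.setdefault(row.id, _variant_from_row(row))

    out = []
    for vid, r2s in r2_by_variant.items():
        if vid == index.variant.id or max(r2s.values()) >= r2_min:
            out.append(CorrelatedSNP(index.variant.id, variant_rows[vid], r2s))
    out.sort(key=lambda c: (c.variant.chrom, c.variant.pos, c.variant.id))
    return out


def intersect_populations(
    corr: list[CorrelatedSNP],
    populations: set[str],
    r2_min: float = 0.5,
    r2_high: float = 0.8,
) -> list[CorrelatedSNP]:
    """Flag proxies correlated with their index in every listed population.

    Tier "shared" means r^2 >= r2_min in all populations; "shared_high"
    raises the bar to r2_high.  An empty result is valid.  Records lacking
    a population are excluded (r^2 unknown there); if some requested
    population appears in no record at all, that is an error.
    """
    pops = set(populations)
    seen = set().union(*(set(c.r2) for c in corr)) if corr else set()
    missing = pops - seen
    if missing:
        raise KeyError(f"populations absent from every record: {sorted(missing)}")
    out = []
    for c in corr:
        if not pops.issubset(c.r2):
            continue
        vals = [c.r2[p] for p in pops]
        if min(vals) >= r2_high:
            out.append(replace(c, tier="shared_high"))
        elif min(vals) >= r2_min:
            out.append(replace(c, tier="shared"))
    return out


def annotate_biofeatures(snps: list[CorrelatedSNP], tracks: TrackSet) -> list[AnnotatedSNP]:
    """Attach biofeature memberships (point-in-interval, half-open) to SNPs.

    SNPs outside every track are retained with an empty membership set and
    class "unclassified"; downstream class counts drop them.
    """
    out = []
    for snp in snps:
        member = tracks.memberships(snp.variant.chrom, snp.variant.pos0)
        out.append(AnnotatedSNP(snp, frozenset(member)))
    return out


def promoter_track(tss: IntervalTrack,
                   upstream: int = PROMOTER_UPSTREAM,
                   downstream: int = PROMOTER_DOWNSTREAM) -> IntervalTrack:
    """Strand-aware promoter windows around each TSS.

    For a TSS at 0-based position t the window spans [t-1000, t+100] in the
    direction of transcription: on the minus strand that is [t-100, t+1000].
    """
    if "strand" not in tss.frame.columns:
        raise ValueError("TSS track must carry a strand column")
    rows = []
    for r in tss.frame.itertuples():
        t = int(r.start)
        if r.strand == "+":
            lo, hi = t - upstream, t + downstream + 1
        elif r.strand == "-":
            t = int(r.end) - 1
            lo, hi = t - downstream, t + upstream + 1
        else:
            raise ValueError(f"TSS with invalid strand {r.strand!r}")
        rows.append((r.chrom, max(lo, 0), hi))
    return IntervalTrack("promoter", pd.DataFrame(rows, columns=["chrom", "start", "end"]))


def classify_functional(
    annotated: list[AnnotatedSNP],
    gene_tracks: dict[str, IntervalTrack],
) -> list[AnnotatedSNP]:
    """Assign each SNP to one putative functional class by precedence.

    ``gene_tracks`` must provide 'tss' (with strand), 'coding_exon', 'utr3',
    'utr5' and 'mir_target' tracks.  The full biofeature membership set is
    preserved on every SNP.
    """
    required = {"tss", "coding_exon", "utr3", "utr5", "mir_target"}
    missing = required - set(gene_tracks)
    if missing:
        raise ValueError(f"gene tracks missing: {sorted(missing)}")
    promoters = promoter_track(gene_tracks["tss"])
    out = []
    for a in annotated:
        chrom, p0 = a.variant.chrom, a.variant.pos0
        in_utr = (gene_tracks["utr3"].contains_point(chrom, p0)
                  or gene_tracks["utr5"].contains_point(chrom, p0))
        if gene_tracks["coding_exon"].contains_point(chrom, p0):
            cls = "coding_exon"
        elif in_utr and gene_tracks["mir_target"].contains_point(chrom, p0):
            cls = "mir_utr"
        elif promoters.contains_point(chrom, p0):
            cls = "promoter"
        elif a.memberships:
            cls = "enhancer"
        else:
            cls = "unclassified"
        out.append(replace(a, functional_class=cls))
    return out


class _UnionFind:
    def __init__(self, items):
        self.parent = {i: i for i in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def merge_loci(
    indexes: list[IndexSNP],
    corr_tables: dict[str, list[CorrelatedSNP]],
    panels: dict[str, HaplotypePanel],
    merge_r2: float = 0.5,
    shared_min: int = 3,
) -> list[Locus]:
    """Group index SNPs into risk loci by transitive closure (union-find).

    Two indexes merge when their pairwise r^2 reaches ``merge_r2`` in any
    shared reporting population, or when they share at least ``shared_min``
    correlated SNPs.  Loci are numbered by genomic order of their leftmost
    member.
    """
    ids = [ix.variant.id for ix in indexes]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate index SNP ids")
    by_id = {ix.variant.id: ix for ix in indexes}
    uf = _UnionFind(ids)
    for i, a in enumerate(indexes):
        for b in indexes[i + 1:]:
            shared_pops = set(a.populations) & set(b.populations)
            linked = False
            for pop in sorted(shared_pops):
                panel = panels[pop]
                if a.variant.id in panel and b.variant.id in panel:
                    try:
                        r2 = r2_from_columns(panel.column(a.variant.id),
                                             panel.column(b.variant.id))
                    except MonomorphicVariantError:
                        continue
                    if r2 >= merge_r2:
                        linked = True
                        break
            if not linked:
                pa = {c.variant.id for c in corr_tables.get(a.variant.id, [])}
                pb = {c.variant.id for c in corr_tables.get(b.variant.id, [])}
                linked = len(pa & pb) >= shared_min
            if linked:
                uf.union(a.variant.id, b.variant.id)

    groups: dict[str, list[str]] = {}
    for vid in ids:
        groups.setdefault(uf.find(vid), []).append(vid)
    ordered = sorted(groups.values(),
                     key=lambda g: min((by_id[v].variant.chrom, by_id[v].variant.pos)
                                       for v in g))
    loci = []
    for k, members in enumerate(ordered, start=1):
        merged = sorted({c.variant.id for m in members
                         for c in corr_tables.get(m, [])})
        genes = tuple(sorted({g for m in members for g in by_id[m].genes}))
        loci.append(Locus(k, tuple(sorted(members)), tuple(merged), genes))
    return loci


def snp_biofeature_matrix(annotated: list[AnnotatedSNP]) -> pd.DataFrame:
    """Binary SNP x biofeature membership matrix (sorted labels)."""
    snps = sorted({a.variant.id for a in annotated})
    tracks = sorted(set().union(*(a.memberships for a in annotated)) or set())
    mat = pd.DataFrame(0, index=snps, columns=tracks, dtype=int)
    for a in annotated:
        for t in a.memberships:
            mat.loc[a.variant.id, t] = 1
    return mat


def cluster_matrix(matrix: pd.DataFrame):
    """Agglomerative clustering of the membership matrix.

    Jaccard distance with average linkage on both axes; rows and columns are
    label-sorted before linkage so the result is deterministic regardless of
    input order.  Returns a dict with row/column leaf orderings and the two
    scipy linkage matrices.
    """
    from scipy.cluster import hierarchy
    from scipy.spatial.distance import pdist

    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need at least 2 SNPs and 2 tracks to cluster")
    if not matrix.to_numpy().any():
        raise ValueError("all-zero membership matrix cannot be clustered")
    m = matrix.sort_index(axis=0).sort_index(axis=1)
    data = m.to_numpy(dtype=bool)
    row_link = hierarchy.average(pdist(data, metric="jaccard"))
    col_link = hierarchy.average(pdist(data.T, metric="jaccard"))
    row_order = [m.index[i] for i in hierarchy.leaves_list(row_link)]
    col_order = [m.columns[i] for i in hierarchy.leaves_list(col_link)]
    return {"row_order": row_order, "col_order": col_order,
            "row_linkage": row_link, "col_linkage": col_link,
            "matrix": m.loc[row_order, col_order]}


def annotated_table(annotated: list[AnnotatedSNP]) -> pd.DataFrame:
    """Tidy per-SNP annotation table for TSV export."""
    rows = []
    for a in annotated:
        v = a.variant
        row = {"id": v.id, "chrom": v.chrom, "pos": v.pos, "ref": v.ref,
               "alt": v.alt, "index_snp": a.snp.index_id,
               "class": a.functional_class,
               "biofeatures": ",".join(sorted(a.memberships)) or "."}
        for pop, r2 in sorted(a.snp.r2.items()):
            row[f"r2_{pop}"] = r2
        rows.append(row)
    return pd.DataFrame(rows)
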