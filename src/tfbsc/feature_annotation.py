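"""Per-site covariates: promoter assignment, position, context, redundancy
and regulator/target annotations.

Each binding site is assigned to the nearest gene whose transcription start
site (TSS) lies downstream of the site in that gene's reading orientation,
within 1000 bp; a site sitting in the intergenic region between two
divergently transcribed genes and within range of both TSSs is assigned to
both, and contributes one analysis row per assignment.  Distances are
measured from the site midpoint along the gene's reading orientation,
floored at zero for sites overlapping the TSS.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io_formats import BindingSite, GeneAnnotation, ReferenceBundle, Thresholds

logger = logging.getLogger("tfbsc")

__all__ = [
    "assign_promoters",
    "distance_to_tss",
    "compute_context_flags",
    "redundancy_counts",
    "copy_number_class",
    "n_tfs_class",
    "annotate_bundle",
    "GeneIndex",
]

COPY_CLASSES = ("1", "2", "3", "4-5", "6+")
NTF_CLASSES = ("1", "2", "3", "4", "5", "6-7", "8-9", "10-12", "13+")


def copy_number_class(n: int) -> str:
    """Bin a per-promoter per-TF site count into the 1/2/3/4-5/6+ classes."""
    if n <= 3:
        return str(n)
    return "4-5" if n <= 5 else "6+"


def n_tfs_class(n: int) -> str:
    """Bin the number of distinct TFs targeting a promoter."""
    if n <= 5:
        return str(n)
    if n <= 7:
        return "6-7"
    if n <= 9:
        return "8-9"
    if n <= 12:
        return "10-12"
    return "13+"


class GeneIndex:
    """Per-chromosome sorted TSS index for fast promoter assignment."""

    def __init__(self, genes: list):
        self._by_chrom: dict = {}
        for g in genes:
            self._by_chrom.setdefault(g.chrom, []).append(g)
        for chrom, glist in self._by_chrom.items():
            glist.sort(key=lambda g: (g.tss, g.gene_id))
            self._by_chrom[chrom] = (np.array([g.tss for g in glist]), glist)

    def near(self, chrom: str, lo: int, hi: int) -> list:
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return []
        tss, glist = entry
        i, j = np.searchsorted(tss, [lo, hi])
        return glist[i:j]


def distance_to_tss(site: BindingSite, gene: GeneAnnotation) -> float:
    """Distance from site midpoint to the TSS along the gene's orientation,
    floored at zero."""
    mid = site.midpoint
    raw = (gene.tss - mid) if gene.strand == "+" else (mid - gene.tss)
    return max(raw, 0.0)


def _eligible(site: BindingSite, gene: GeneAnnotation, promoter_bp: int) -> bool:
    mid = site.midpoint
    raw = (gene.tss - mid) if gene.strand == "+" else (mid - gene.tss)
    if 0 <= raw <= promoter_bp:
        return True
    # site interval overlapping the TSS counts as distance 0
    return raw < 0 and site.start <= gene.tss < site.end


def assign_promoters(
    site: BindingSite, genes, promoter_bp: int = 1000
) -> list[tuple[GeneAnnotation, float]]:
    """Assigned (gene, distance) pairs for a site: the nearest eligible gene,
    or both flanking genes of a divergent intergenic region."""
    index = genes if isinstance(genes, GeneIndex) else GeneIndex(genes)
    mid = int(site.midpoint)
    candidates = index.near(site.chrom, mid - promoter_bp - site.length,
                            mid + promoter_bp + site.length)
    best = {}
    for g in candidates:
        if not _eligible(site, g, promoter_bp):
            continue
        d = distance_to_tss(site, g)
        cur = best.get(g.strand)
        if cur is None or d < cur[1] or (d == cur[1] and g.gene_id < cur[0].gene_id):
            best[g.strand] = (g, d)
    # one eligible reading direction -> single assignment; both -> the site
    # lies between two divergently transcribed genes and serves both.
    out = [best[s] for s in "+-" if s in best]
    out.sort(key=lambda gd: (gd[1], gd[0].gene_id))
    return out


def _interval_overlaps(a_start, a_end, b_start, b_end) -> bool:
    return a_start < b_end and b_start < a_end


def compute_context_flags(
    site: BindingSite,
    all_sites: list,
    nfr_intervals: list,
    chrom_lengths: dict,
    assigned: list,
    thresholds: Thresholds = Thresholds(),
) -> dict:
    """Subtelomere, NFR, overlap, and divergent-promoter flags for one site.

    ``assigned`` is the output of :func:`assign_promoters`.  ``in_nfr`` is
    returned per assignment since the NFR window is anchored at the
    assigned TSS.
    """
    L = chrom_lengths[site.chrom]
    subtel = min(site.start, L - site.end) < thresholds.subtelomere_bp
    overlaps = any(
        s.site_id != site.site_id
        and s.chrom == site.chrom
        and _interval_overlaps(site.start, site.end, s.start, s.end)
        for s in all_sites
    )
    in_nfr = {}
    for gene, _d in assigned:
        if gene.strand == "+":
            w_lo, w_hi = gene.tss - thresholds.nfr_window_bp, gene.tss
        else:
            w_lo, w_hi = gene.tss + 1, gene.tss + 1 + thresholds.nfr_window_bp
        flag = False
        for chrom, n_lo, n_hi in nfr_intervals:
            if (
                chrom == site.chrom
                and _interval_overlaps(n_lo, n_hi, w_lo, w_hi)
                and _interval_overlaps(site.start, site.end, n_lo, n_hi)
            ):
                flag = True
                break
        in_nfr[gene.gene_id] = flag
    return {
        "subtelomeric": subtel,
        "overlaps_other_site": overlaps,
        "divergent_promoter": len(assigned) == 2,
        "in_nfr": in_nfr,
    }


def redundancy_counts(promoter_sites: list) -> tuple[dict, int]:
    """(copy number per TF, number of distinct TFs) for one promoter."""
    if not promoter_sites:
        raise ValueError("promoter has no sites")
    copy = {}
    for s in promoter_sites:
        copy[s.tf_id] = copy.get(s.tf_id, 0) + 1
    return copy, len(copy)


def _overlap_flags(sites: list) -> dict:
    """site_id -> overlaps another site (any TF), by plane sweep."""
    flags = {s.site_id: False for s in sites}
    by_chrom: dict = {}
    for s in sites:
        by_chrom.setdefault(s.chrom, []).append(s)
    for slist in by_chrom.values():
        slist.sort(key=lambda s: s.start)
        max_end = -1
        max_end_id = None
        for s in slist:
            if s.start < max_end:
                flags[s.site_id] = True
                flags[max_end_id] = True
            if s.end > max_end:
                max_end, max_end_id = s.end, s.site_id
    return flags


def annotate_bundle(
    bundle: ReferenceBundle, collapse_divergent: bool = False
) -> pd.DataFrame:
    """The full covariate table, one row per (site, assigned promoter).

    With ``collapse_divergent`` only the nearest assignment of each site is
    kept (the sensitivity analysis that excludes double counting).
    Sites with no gene within range are excluded (and counted in the log).
    """
    thr = bundle.thresholds
    index = GeneIndex(bundle.genes)
    chrom_lengths = bundle.chrom_lengths
    gene_by_id = {g.gene_id: g for g in bundle.genes}
    tf_info = bundle.tf_table.set_index("tf_id")

    assignments = {}
    for s in bundle.sites:
        assigned = assign_promoters(s, index, thr.promoter_bp)
        if assigned:
            assignments[s.site_id] = assigned
    n_unassigned = len(bundle.sites) - len(assignments)
    if n_unassigned:
        logger.info("%d sites with no promoter within %d bp excluded",
                    n_unassigned, thr.promoter_bp)

    # promoter composition from assigned sites
    promoter_sites: dict = {}
    for s in bundle.sites:
        for gene, _d in assignments.get(s.site_id, []):
            promoter_sites.setdefault(gene.gene_id, []).append(s)
    promoter_tfs = {g: {s.tf_id for s in ss} for g, ss in promoter_sites.items()}

    # negative genetic-interaction partner co-occurrence per (promoter, tf)
    negative_partners: dict = {}
    for pair, score in bundle.emap.items():
        if score < thr.emap_negative and len(pair) == 2:
            a, b = sorted(pair)
            negative_partners.setdefault(a, set()).add(b)
            negative_partners.setdefault(b, set()).add(a)

    overlap = _overlap_flags(bundle.sites)
    nfr_by_chrom: dict = {}
    for chrom, lo, hi in bundle.nfr_intervals:
        nfr_by_chrom.setdefault(chrom, []).append((lo, hi))

    from .motif_scoring import strength as _strength

    rows = []
    for s in bundle.sites:
        assigned = assignments.get(s.site_id)
        if not assigned:
            continue
        if collapse_divergent:
            assigned = assigned[:1]
        pssm = bundle.pssms[s.tf_id]
        site_strength = _strength(s.seq, pssm)
        L = chrom_lengths[s.chrom]
        subtel = min(s.start, L - s.end) < thr.subtelomere_bp
        divergent = len(assignments[s.site_id]) == 2
        tf_row = tf_info.loc[s.tf_id]
        for gene, d in assigned:
            copy, n_tfs = redundancy_counts(promoter_sites[gene.gene_id])
            if gene.strand == "+":
                w_lo, w_hi = gene.tss - thr.nfr_window_bp, gene.tss
            else:
                w_lo, w_hi = gene.tss + 1, gene.tss + 1 + thr.nfr_window_bp
            in_nfr = any(
                _interval_overlaps(n_lo, n_hi, w_lo, w_hi)
                and _interval_overlaps(s.start, s.end, n_lo, n_hi)
                for n_lo, n_hi in nfr_by_chrom.get(s.chrom, [])
            )
            partners = negative_partners.get(s.tf_id, set())
            emap_partner = bool(partners & (promoter_tfs[gene.gene_id] - {s.tf_id}))
            rows.append(
                {
                    "site_id": s.site_id,
                    "tf_id": s.tf_id,
                    "gene_id": gene.gene_id,
                    "strength": site_strength,
                    "distance": d,
                    "in_nfr": in_nfr,
                    "overlaps_other_site": overlap[s.site_id],
                    "divergent_promoter": divergent,
                    "copy_number": copy[s.tf_id],
                    "copy_class": copy_number_class(copy[s.tf_id]),
                    "n_tfs_in_promoter": n_tfs,
                    "ntf_class": n_tfs_class(n_tfs),
                    "subtelomeric": subtel,
                    "target_essential": gene.essential,
                    "target_overexpression_harmful": gene.overexpression_harmful,
                    "tf_essential": bool(tf_row["essential"]),
                    "target_is_regulator": gene.regulator_class,
                    "tf_hierarchy": tf_row["hierarchy"],
                    "emap_partner": emap_partner,
                    "n_assignments": len(assignments[s.site_id]),
                }
            )
    return pd.DataFrame(rows)
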