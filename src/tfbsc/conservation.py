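"""Conservation calls for binding sites and regulatory edges.

Within-species conservation requires functional conservation (strength at
least the 60% threshold) in every strain of the panel, rebuilding each
strain's site sequence from quality-filtered SNVs.  Between-species
conservation requires functional conservation in at least 2 of 3 related
species, from pre-extracted orthologous site sequences; a missing sequence
counts as not conserved.  An edge (TF -> promoter interaction) is conserved
when at least one of its sites is.  SNPs per base pair exclude motif gap
positions and overlapping sites; the flanking control measures divergence
over the 10 bases downstream of a site that fall outside every known site.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io_formats import BindingSite, ReferenceBundle, StrainVariantTable
from .motif_scoring import PSSM, is_functionally_conserved, scan_promoter, strength

logger = logging.getLogger("tfbsc")

__all__ = [
    "strain_site_sequence",
    "within_species_call",
    "between_species_call",
    "edge_conserved",
    "snps_per_bp",
    "flanking_divergence",
    "detect_gained_sites",
    "call_conservation",
    "OVERLAP_SENTINEL",
]

# sentinel for sites excluded from the SNPs/bp and flank analyses
OVERLAP_SENTINEL = float("nan")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _genomic_to_motif_index(site: BindingSite, pos: int) -> int:
    """Map a genomic position inside the site to a motif index on the
    annotated strand."""
    off = pos - site.start
    return off if site.strand == "+" else site.length - 1 - off


def strain_site_sequence(
    site: BindingSite,
    strain_id: str,
    variants: StrainVariantTable,
    genome: dict,
    quality_p: float = 1e-3,
) -> str:
    """The site sequence carried by one strain, on the annotated strand.

    Quality-passing SNVs (p below `quality_p`) of the strain are
    substituted into the reference; everything else is reference.
    """
    sub = variants.in_interval(site.chrom, site.start, site.end,
                               max_quality_p=quality_p)
    sub = sub[sub["strain_id"] == strain_id]
    seq = list(genome[site.chrom][site.start:site.end])
    for row in sub.itertuples(index=False):
        if genome[site.chrom][row.pos] != row.ref:
            raise ValueError(
                f"variant REF mismatch at {site.chrom}:{row.pos + 1}"
            )
        seq[row.pos - site.start] = row.alt
    out = "".join(seq)
    if site.strand == "-":
        out = out.translate(_COMPLEMENT)[::-1]
    return out


def within_species_call(
    site: BindingSite,
    strain_ids: list,
    variants: StrainVariantTable,
    genome: dict,
    pssm: PSSM,
    tau: float = 0.6,
    quality_p: float = 1e-3,
) -> tuple[bool, int]:
    """(conserved in every strain, number of strains evaluated)."""
    if not strain_ids:
        raise ValueError("within-species call requires at least one strain")
    sub = variants.in_interval(site.chrom, site.start, site.end,
                               max_quality_p=quality_p)
    if len(sub) == 0:
        # no passing variant anywhere in the site: all strains carry the
        # reference sequence, which passes the threshold by precondition
        return True, len(strain_ids)
    ref = genome[site.chrom][site.start:site.end]
    positions = sub["pos"].to_numpy()
    alts = sub["alt"].to_numpy()
    for _strain, idx in sub.groupby("strain_id", sort=True).indices.items():
        seq = list(ref)
        for j in idx:
            seq[positions[j] - site.start] = alts[j]
        out = "".join(seq)
        if site.strand == "-":
            out = out.translate(_COMPLEMENT)[::-1]
        if not is_functionally_conserved(out, pssm, tau):
            return False, len(strain_ids)
    return True, len(strain_ids)


def between_species_call(
    site: BindingSite,
    species_sequences: dict,
    species_ids: list,
    pssm: PSSM,
    tau: float = 0.6,
) -> bool:
    """Functionally conserved in at least 2 of the additional species;
    a missing orthologous sequence counts as not conserved."""
    n_conserved = 0
    for sp in species_ids:
        seq = species_sequences.get((site.site_id, sp))
        if seq is not None and is_functionally_conserved(seq, pssm, tau):
            n_conserved += 1
    return n_conserved >= 2


def edge_conserved(site_flags: list) -> bool:
    """An interaction is retained if any of its sites is conserved."""
    if not site_flags:
        raise ValueError("an edge exists only where binding was observed")
    return any(site_flags)


def _nongap_genomic_positions(site: BindingSite, pssm: PSSM) -> set:
    out = set()
    for i in range(site.length):
        if i in pssm.gap_positions:
            continue
        out.add(site.start + i if site.strand == "+" else site.end - 1 - i)
    return out


def snps_per_bp(
    site: BindingSite,
    variants: StrainVariantTable,
    all_sites: list,
    pssm: PSSM,
    quality_p: float = 1e-3,
) -> float:
    """Distinct polymorphic non-gap positions over the non-gap motif length.

    Sites overlapping another site return NaN and are excluded from this
    analysis, as are bases in motif gaps.
    """
    for other in all_sites:
        if (
            other.site_id != site.site_id
            and other.chrom == site.chrom
            and other.start < site.end
            and site.start < other.end
        ):
            return OVERLAP_SENTINEL
    nongap = _nongap_genomic_positions(site, pssm)
    if not nongap:
        raise ValueError(f"site {site.site_id} has no non-gap positions")
    sub = variants.in_interval(site.chrom, site.start, site.end,
                               max_quality_p=quality_p)
    poly = set(sub["pos"]) & nongap
    return len(poly) / len(nongap)


def flanking_divergence(
    site: BindingSite,
    variants: StrainVariantTable,
    all_sites: list,
    chrom_lengths: dict,
    window: int = 10,
    quality_p: float = 1e-3,
) -> float:
    """SNPs/bp over the <=`window` bases downstream of the site (in its
    annotated-strand orientation) that lie outside every known site."""
    L = chrom_lengths[site.chrom]
    if site.strand == "+":
        lo, hi = site.end, min(site.end + window, L)
    else:
        lo, hi = max(site.start - window, 0), site.start
    positions = set(range(lo, hi))
    for other in all_sites:
        if other.chrom == site.chrom:
            positions -= set(range(other.start, other.end))
    if not positions:
        return OVERLAP_SENTINEL
    sub = variants.in_interval(site.chrom, lo, hi, max_quality_p=quality_p)
    poly = set(sub["pos"]) & positions
    return len(poly) / len(positions)


def detect_gained_sites(
    promoter: tuple,
    tf_id: str,
    pssm: PSSM,
    strain_ids: list,
    variants: StrainVariantTable,
    genome: dict,
    tau: float = 0.6,
    quality_p: float = 1e-3,
) -> list[dict]:
    """Motif instances present in a strain's promoter but absent from the
    reference (binding-site turnover / gain).

    `promoter` is a (chrom, start, end) interval.  Returns one record per
    (strain, offset, strand) hit that has no reference hit.
    """
    chrom, start, end = promoter
    ref_seq = genome[chrom][start:end]
    if len(ref_seq) < pssm.length:
        return []
    ref_hits = {(off, strand) for off, strand, _ in scan_promoter(ref_seq, pssm, tau)}
    sub = variants.in_interval(chrom, start, end, max_quality_p=quality_p)
    gains = []
    positions = sub["pos"].to_numpy()
    alts = sub["alt"].to_numpy()
    strain_set = set(strain_ids)
    for strain, idx in sorted(sub.groupby("strain_id", sort=True).indices.items()):
        if strain not in strain_set:
            continue
        seq = list(ref_seq)
        for j in idx:
            seq[positions[j] - start] = alts[j]
        for off, strand, st in scan_promoter("".join(seq), pssm, tau):
            if (off, strand) not in ref_hits:
                gains.append(
                    {
                        "chrom": chrom, "promoter_start": start,
                        "tf_id": tf_id, "strain_id": strain,
                        "offset": off, "strand": strand, "strength": st,
                    }
                )
    return gains


def call_conservation(
    bundle: ReferenceBundle,
    features: pd.DataFrame | None = None,
    detect_gains: bool = True,
) -> pd.DataFrame:
    """Per-site conservation table for a full bundle.

    Columns: within, between, identical_in_all_strains, snps_per_bp,
    flank_snps_per_bp, reference_below_threshold, n_strains,
    gained_alternative_site.  Sites whose reference sequence itself fails
    the threshold are flagged and receive no within/between call.
    """
    thr = bundle.thresholds
    chrom_lengths = bundle.chrom_lengths

    # precomputed structures so the per-site work stays O(log n)
    from .feature_annotation import _overlap_flags

    overlap = _overlap_flags(bundle.sites)
    covered = {c: np.zeros(n, dtype=bool) for c, n in chrom_lengths.items()}
    for s in bundle.sites:
        covered[s.chrom][s.start:s.end] = True

    rows = []
    for s in bundle.sites:
        pssm = bundle.pssms[s.tf_id]
        ref_ok = strength(s.seq, pssm) >= thr.tau
        if ref_ok:
            within, n_eval = within_species_call(
                s, bundle.strain_ids, bundle.variants, bundle.genome,
                pssm, thr.tau, thr.quality_p,
            )
            between = between_species_call(
                s, bundle.species_sequences, bundle.species_ids, pssm, thr.tau
            )
        else:
            within = between = None
            n_eval = 0

        nongap = _nongap_genomic_positions(s, pssm)
        sub = bundle.variants.in_interval(
            s.chrom, s.start, s.end, max_quality_p=thr.quality_p
        )
        n_poly_nongap = len(set(sub["pos"]) & nongap)
        if overlap[s.site_id]:
            spb = OVERLAP_SENTINEL
        else:
            spb = n_poly_nongap / len(nongap)

        L = chrom_lengths[s.chrom]
        if s.strand == "+":
            f_lo, f_hi = s.end, min(s.end + thr.flank_bp, L)
        else:
            f_lo, f_hi = max(s.start - thr.flank_bp, 0), s.start
        mask = covered[s.chrom][f_lo:f_hi]
        retained = int((~mask).sum())
        if retained == 0:
            flank = OVERLAP_SENTINEL
        else:
            fsub = bundle.variants.in_interval(
                s.chrom, f_lo, f_hi, max_quality_p=thr.quality_p
            )
            free = {p for p in fsub["pos"] if not covered[s.chrom][p]}
            flank = len(free) / retained
        rows.append(
            {
                "site_id": s.site_id,
                "tf_id": s.tf_id,
                "within": within,
                "between": between,
                "identical_in_all_strains": n_poly_nongap == 0,
                "n_strains": n_eval,
                "snps_per_bp": spb,
                "flank_snps_per_bp": flank,
                "reference_below_threshold": not ref_ok,
            }
        )
    calls = pd.DataFrame(rows)

    if detect_gains:
        from .feature_annotation import GeneIndex, assign_promoters

        index = GeneIndex(bundle.genes)
        # one scan per (promoter, TF) edge present in the site map
        edges = {}
        for s in bundle.sites:
            for gene, _d in assign_promoters(s, index, thr.promoter_bp):
                edges.setdefault((gene.gene_id, s.tf_id), gene)
        gene_gain = {}
        for (gene_id, tf_id), gene in sorted(edges.items()):
            if gene.strand == "+":
                p_lo, p_hi = max(gene.tss - thr.promoter_bp, 0), gene.tss
            else:
                p_lo = gene.tss + 1
                p_hi = min(gene.tss + 1 + thr.promoter_bp,
                           chrom_lengths[gene.chrom])
            gains = detect_gained_sites(
                (gene.chrom, p_lo, p_hi), tf_id, bundle.pssms[tf_id],
                bundle.strain_ids, bundle.variants, bundle.genome,
                thr.tau, thr.quality_p,
            )
            gene_gain[(gene_id, tf_id)] = len(gains) > 0
        # a site is marked if any of its promoters gained an alternative
        # site for its TF in at least one strain
        site_gain = {}
        for s in bundle.sites:
            flags = [
                gene_gain.get((gene.gene_id, s.tf_id), False)
                for gene, _d in assign_promoters(s, index, thr.promoter_bp)
            ]
            site_gain[s.site_id] = any(flags)
        calls["gained_alternative_site"] = calls["site_id"].map(site_gain)
    else:
        calls["gained_alternative_site"] = False
    logger.info(
        "conservation calls: %d sites, %.1f%% within, %.1f%% between",
        len(calls),
        100 * calls["within"].fillna(False).mean(),
        100 * calls["between"].fillna(False).mean(),
    )
    return calls
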