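"""Synthetic reference bundles with a planted conservation model.

The generator emulates the study system end to end: a compact yeast-like
genome with promoters, divergent gene pairs and subtelomeric regions;
PSSMs with one strict-majority base per informative column; binding sites
planted in promoters so every reference site passes the 60% strength
threshold; a strain panel and three related species.  Conservation is not
emitted as labels: each site's per-comparison retention probability comes
from a logistic model over the site's own covariates (``p = logistic(c +
beta_true . x)``), the outcome is drawn, and the generator then realizes it
at the sequence level - retained sites receive only mutations that keep
the score above threshold (or none), lost sites receive score-breaking
substitutions in one or more strains, or in enough species to invert the
2-of-3 rule.  Background SNPs, quality-failing variant records, and
gained (turnover) motif instances in strain promoters are sprinkled on
top.  Downstream pipeline calls re-derived from the sequences must then
reproduce the truth table exactly, which is the generator's self-
consistency contract.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import integrated_model as im
from .feature_annotation import annotate_bundle
from .io_formats import (
    BindingSite,
    GeneAnnotation,
    ReferenceBundle,
    StrainVariantTable,
    Thresholds,
    write_reference_bundle,
    write_tsv_table,
)
from .motif_scoring import BASES, PSSM, encode_sequence

logger = logging.getLogger("tfbsc")

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "DEFAULT_BETA",
    "generate_pssm_set",
    "generate_genome_and_genes",
    "plant_binding_sites",
    "simulate_divergence",
    "generate_bundle",
    "write_simulation",
]

_COMP = np.array([3, 2, 1, 0], dtype=np.uint8)

# planted effects on the model's design columns: directions follow the
# study system (stronger, divergent, promoter-proximal, top-of-hierarchy,
# essential-TF and regulator-target sites more conserved; subtelomeric,
# TF-redundant and epistatic-partner sites less conserved)
DEFAULT_BETA = {
    "strength": 4.0,
    "subtelomeric": -0.8,
    "divergent": 0.5,
    "distance_1": -0.5,
    "n_tfs": -0.07,
    "hierarchy_lin": 0.5,
    "tf_essential": 0.5,
    "overlaps_other_site": 0.4,
    "target_is_regulator": 0.3,
    "emap_partner": -0.6,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generator (defaults emulate the real data
    scale at desk size: 3 chromosomes x 300 kb, 40 TFs, 2,000 genes,
    10,000 sites, 36 strains, 3 species)."""

    n_chromosomes: int = 3
    chromosome_length: int = 300_000
    n_tfs: int = 40
    n_genes: int = 2000
    n_sites: int = 10_000
    motif_length_range: tuple = (7, 12)
    ic_per_column_range: tuple = (0.8, 1.6)   # bits per informative column
    gap_probability: float = 0.25             # motifs >= 9 bp may get one gap
    fraction_divergent: float = 0.3
    fraction_essential_genes: float = 0.18
    fraction_slow_growth: float = 0.10
    fraction_overexpression_harmful: float = 0.15
    fraction_tf_class_genes: float = 0.05
    fraction_non_tf_regulators: float = 0.08
    fraction_essential_tfs: float = 0.2
    fraction_unassigned_hierarchy: float = 0.0
    hierarchy_proportions: tuple = (0.25, 0.5, 0.25)   # top, core, bottom
    n_strains: int = 36
    n_species: int = 3
    background_mutation_rate: float = 3e-4    # per strain per bp outside sites
    species_benign_rate: float = 0.03         # per bp, retained species copies
    benign_site_fraction: float = 0.05        # retained sites with a benign SNP
    decoy_fraction: float = 0.03              # retained sites with a quality-failing SNP
    quality_fail_fraction: float = 0.1        # background records failing the filter
    gain_fraction: float = 0.03               # promoters receiving a gained site
    overlap_fraction: float = 0.05            # sites deliberately overlapping
    nfr_fraction: float = 0.5
    hub_promoter_fraction: float = 0.05
    n_emap_pairs: int = 150
    tss_margin: int = 1500
    base_freqs: tuple = (0.31, 0.19, 0.19, 0.31)
    missing_species_fraction: float = 0.0
    beta_true: dict = field(default_factory=lambda: dict(DEFAULT_BETA))
    # intercepts chosen so the marginal conservation rates under the
    # default conditions sit near the study system's 92% (within) and
    # 29% (between)
    intercept_within: float = -0.12
    intercept_between: float = -4.08
    thresholds: Thresholds = field(default_factory=Thresholds)

    def validate(self):
        for name in (
            "fraction_divergent", "fraction_essential_genes", "gain_fraction",
            "benign_site_fraction", "quality_fail_fraction", "nfr_fraction",
            "overlap_fraction", "missing_species_fraction",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.chromosome_length <= 2 * self.thresholds.subtelomere_bp:
            raise ValueError(
                "chromosome shorter than twice the subtelomere width: no "
                "interior region would exist"
            )
        if min(self.motif_length_range) < 5:
            raise ValueError("motifs must be at least 5 bp")
        lo, hi = self.ic_per_column_range
        if not (0 < lo <= hi < 2):
            raise ValueError("per-column information content must lie in (0, 2) bits")
        if abs(sum(self.hierarchy_proportions) - 1) > 1e-9:
            raise ValueError("hierarchy proportions must sum to 1")


@dataclass
class SimulationResult:
    config: SimulationConfig
    bundle: ReferenceBundle
    truth: pd.DataFrame
    gains: pd.DataFrame
    features: pd.DataFrame    # per (site, promoter) covariate rows
    design: pd.DataFrame      # site-level design matrix used by the plant


# ---------------------------------------------------------------------------
# PSSMs

def _q_for_ic(ic: float) -> float:
    """Majority-base probability giving `ic` bits for a (q, rest-equal)
    column; solved by bisection on the increasing IC(q)."""

    def f(q):
        r = (1 - q) / 3
        return 2 + q * np.log2(q) + (1 - q) * np.log2(r)

    lo, hi = 0.2500001, 1 - 1e-9
    if not (f(lo) <= ic <= 2.0):
        raise ValueError(f"per-column information content {ic} infeasible")
    for _ in range(60):
        mid = (lo + hi) / 2
        if f(mid) < ic:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def generate_pssm_set(cfg: SimulationConfig, rng: np.random.Generator) -> dict:
    """One strict-majority-consensus PSSM per TF, information content per
    informative column drawn from the configured range."""
    lo, hi = cfg.ic_per_column_range
    pssms = {}
    for t in range(cfg.n_tfs):
        tf_id = f"TF{t + 1:03d}"
        L = int(rng.integers(cfg.motif_length_range[0],
                             cfg.motif_length_range[1] + 1))
        gaps = frozenset()
        if L >= 9 and rng.random() < cfg.gap_probability:
            gaps = frozenset({int(rng.integers(L // 3, 2 * L // 3))})
        probs = np.empty((L, 4))
        for i in range(L):
            if i in gaps:
                probs[i] = 0.25
                continue
            q = _q_for_ic(float(rng.uniform(lo, hi)))
            consensus = int(rng.integers(0, 4))
            probs[i] = (1 - q) / 3
            probs[i, consensus] = q
        pssms[tf_id] = PSSM(tf_id, probs, np.full(4, 0.25), gaps)
    return pssms


# ---------------------------------------------------------------------------
# genome and genes

def generate_genome_and_genes(
    cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[dict, list]:
    """Random genome plus a gene map with divergent pairs, tandem genes and
    subtelomeric genes; strands arranged so that divergent (face-to-face)
    promoters occur only where the divergent-pair fraction asks for them."""
    cfg.validate()
    genome_arrays = {}
    for c in range(cfg.n_chromosomes):
        genome_arrays[f"chr{c + 1}"] = rng.choice(
            4, size=cfg.chromosome_length, p=np.asarray(cfg.base_freqs)
        ).astype(np.uint8)

    per_chrom = [cfg.n_genes // cfg.n_chromosomes] * cfg.n_chromosomes
    for i in range(cfg.n_genes % cfg.n_chromosomes):
        per_chrom[i] += 1
    promoter_bp = cfg.thresholds.promoter_bp

    genes = []
    gidx = 0
    for c, n_c in enumerate(per_chrom):
        chrom = f"chr{c + 1}"
        span = cfg.chromosome_length - 2 * cfg.tss_margin
        if n_c > 0 and span / n_c < 100:
            raise ValueError("gene density infeasible for the chromosome length")
        step = span / max(n_c, 1)
        tss = (cfg.tss_margin
               + (np.arange(n_c) + rng.uniform(0.15, 0.85, n_c)) * step
               ).astype(int)
        strands = np.array([""] * n_c, dtype=object)
        paired = np.zeros(n_c, dtype=bool)
        i = 0
        while i < n_c - 1:
            if (
                rng.random() < cfg.fraction_divergent
                and not paired[i]
                and tss[i + 1] - tss[i] <= 2 * promoter_bp - 100
            ):
                strands[i], strands[i + 1] = "-", "+"
                paired[i] = paired[i + 1] = True
                i += 2
            else:
                i += 1
        for i in range(n_c):
            if strands[i] == "":
                strands[i] = "+" if rng.random() < 0.5 else "-"
        # remove accidental face-to-face promoters: a '+' gene within reach
        # of an upstream unpaired '-' gene would create a divergent
        # intergenic region not requested by fraction_divergent
        last_minus = -10 ** 9
        for i in range(n_c):
            if strands[i] == "+" and not paired[i] and tss[i] - last_minus <= 2 * promoter_bp:
                strands[i] = "-"
            if strands[i] == "-":
                last_minus = tss[i]
        for i in range(n_c):
            gidx += 1
            essential = "none"
            u = rng.random()
            if u < cfg.fraction_essential_genes:
                essential = "essential"
            elif u < cfg.fraction_essential_genes + cfg.fraction_slow_growth:
                essential = "slow_growth"
            u = rng.random()
            if u < cfg.fraction_tf_class_genes:
                reg = "tf"
            elif u < cfg.fraction_tf_class_genes + cfg.fraction_non_tf_regulators:
                reg = "non_tf_regulator"
            else:
                reg = "none"
            hierarchy = "unassigned"
            if reg == "tf":
                hierarchy = str(rng.choice(
                    ["top", "core", "bottom"], p=cfg.hierarchy_proportions
                ))
            genes.append(
                GeneAnnotation(
                    gene_id=f"g{gidx:05d}", chrom=chrom, tss=int(tss[i]),
                    strand=str(strands[i]), essential=essential,
                    overexpression_harmful=bool(
                        rng.random() < cfg.fraction_overexpression_harmful
                    ),
                    regulator_class=reg, hierarchy=hierarchy,
                )
            )
    return genome_arrays, genes


def _promoter_interval(gene: GeneAnnotation, promoter_bp: int, chrom_len: int):
    if gene.strand == "+":
        return max(gene.tss - promoter_bp, 0), gene.tss
    return gene.tss + 1, min(gene.tss + 1 + promoter_bp, chrom_len)


def _sample_site_sequence(
    pssm: PSSM, tau: float, rng: np.random.Generator, max_tries: int = 60
) -> np.ndarray:
    """Draw an encoded sequence from the PSSM columns until it passes the
    strength threshold (consensus as a last resort)."""
    cum = pssm.probs.cumsum(axis=1)
    lo = pssm.log_odds
    idx = np.arange(pssm.length)
    for _ in range(max_tries):
        enc = (rng.random((pssm.length, 1)) < cum).argmax(axis=1).astype(np.uint8)
        if lo[idx, enc].sum() / pssm.max_score >= tau:
            return enc
    return lo[:, :4].argmax(axis=1).astype(np.uint8)


def plant_binding_sites(
    cfg: SimulationConfig,
    genome_arrays: dict,
    genes: list,
    pssms: dict,
    rng: np.random.Generator,
) -> tuple[list, list]:
    """Write binding sites into promoters (every reference site passes the
    threshold), covering the 1/2/3/4-5/6+ copy-number classes, a spread of
    promoter TF counts, deliberate overlaps, and NFR intervals."""
    thr = cfg.thresholds
    tau = thr.tau
    tf_ids = sorted(pssms)
    chrom_len = {c: len(a) for c, a in genome_arrays.items()}

    # occupied = site bodies plus their downstream flanks (placement mask);
    # body marks site bodies only, so deliberate overlaps can verify they
    # touch nothing but their chosen partner
    occupied = {c: np.zeros(n, dtype=bool) for c, n in chrom_len.items()}
    body = {c: np.zeros(n, dtype=bool) for c, n in chrom_len.items()}

    # per-promoter plan covering the redundancy classes; the plan is
    # replenished over several passes when occupancy rejections leave the
    # requested site count unmet
    copy_choices = np.array([1, 2, 3, 4, 5, 6, 7, 8])
    copy_probs = np.array([0.50, 0.20, 0.12, 0.06, 0.045, 0.035, 0.025, 0.015])

    def _make_plan(target):
        plan = []
        planned = 0
        order = rng.permutation(len(genes))
        for gi in order:
            if planned >= target:
                break
            if rng.random() < cfg.hub_promoter_fraction:
                n_tf_p = int(rng.integers(8, 16))
            else:
                n_tf_p = 1 + int(rng.poisson(1.0))
            chosen = rng.choice(len(tf_ids), size=min(n_tf_p, len(tf_ids)),
                                replace=False)
            for t in chosen:
                copies = int(rng.choice(copy_choices, p=copy_probs))
                plan.append((int(gi), tf_ids[t], copies))
                planned += copies
        return plan

    raw_sites = []  # (chrom, start, end, tf_id, strand)
    promoter_last: dict = {}
    n_skipped = 0

    def _plant_entry(gi, tf_id, copies):
        nonlocal n_skipped
        gene = genes[gi]
        pssm = pssms[tf_id]
        L = pssm.length
        p_lo, p_hi = _promoter_interval(gene, thr.promoter_bp,
                                        chrom_len[gene.chrom])
        if p_hi - p_lo < L + thr.flank_bp + 2:
            n_skipped += copies
            return
        occ = occupied[gene.chrom]
        arr = genome_arrays[gene.chrom]
        for _copy in range(copies):
            if len(raw_sites) >= cfg.n_sites:
                return
            placed = False
            prev = promoter_last.get(gi)
            for _try in range(40):
                overlap_mode = (
                    prev is not None and rng.random() < cfg.overlap_fraction
                )
                if overlap_mode:
                    ov = int(rng.integers(1, 4))
                    start = prev[1] - ov  # prev end minus overlap
                else:
                    start = int(rng.integers(p_lo, p_hi - L + 1))
                end = start + L
                strand = "+" if rng.random() < 0.5 else "-"
                flank = (end, min(end + thr.flank_bp, chrom_len[gene.chrom])) \
                    if strand == "+" else (max(start - thr.flank_bp, 0), start)
                if start < 0 or end > chrom_len[gene.chrom]:
                    continue
                if overlap_mode:
                    # may share bases with the chosen partner only
                    if body[gene.chrom][prev[1]:end].any():
                        continue
                elif occ[start:end].any() or occ[flank[0]:flank[1]].any():
                    continue
                enc = _sample_site_sequence(pssm, tau, rng)
                enc_genomic = _COMP[enc][::-1] if strand == "-" else enc
                saved = arr[start:end].copy()
                arr[start:end] = enc_genomic
                if overlap_mode:
                    # the overwrite must not break the overlapped partner
                    _pc, ps, pe, ptf, pstrand = prev[2]
                    pseq = arr[ps:pe]
                    pseq = _COMP[pseq][::-1] if pstrand == "-" else pseq
                    p_pssm = pssms[ptf]
                    p_strength = (
                        p_pssm.log_odds[np.arange(p_pssm.length), pseq].sum()
                        / p_pssm.max_score
                    )
                    if p_strength < tau:
                        arr[start:end] = saved
                        continue
                occ[start:end] = True
                occ[flank[0]:flank[1]] = True
                body[gene.chrom][start:end] = True
                rec = (gene.chrom, start, end, tf_id, strand)
                raw_sites.append(rec)
                promoter_last[gi] = (start, end, rec)
                placed = True
                break
            if not placed:
                n_skipped += 1

    for _pass in range(6):
        if len(raw_sites) >= cfg.n_sites:
            break
        for gi, tf_id, copies in _make_plan(
            int((cfg.n_sites - len(raw_sites)) * 1.15) + 1
        ):
            if len(raw_sites) >= cfg.n_sites:
                break
            _plant_entry(gi, tf_id, copies)
    if n_skipped:
        logger.info("site planting: %d placements skipped after retries", n_skipped)
    if len(raw_sites) < cfg.n_sites * 0.9:
        raise RuntimeError(
            f"could only place {len(raw_sites)} of {cfg.n_sites} sites; "
            "promoters too short for the requested density"
        )

    raw_sites.sort(key=lambda r: (r[0], r[1], r[3]))
    sites = []
    for i, (chrom, start, end, tf_id, strand) in enumerate(raw_sites):
        enc = genome_arrays[chrom][start:end]
        if strand == "-":
            enc = _COMP[enc][::-1]
        seq = "".join(BASES[b] for b in enc)
        sites.append(BindingSite(f"s{i + 1:06d}", chrom, start, end,
                                 tf_id, strand, seq))

    nfr = []
    for gene in genes:
        if rng.random() < cfg.nfr_fraction:
            if gene.strand == "+":
                lo_i = max(gene.tss - thr.nfr_window_bp + 10, 0)
                hi_i = max(gene.tss - 10, lo_i + 1)
            else:
                lo_i = gene.tss + 10
                hi_i = min(gene.tss + thr.nfr_window_bp - 10,
                           chrom_len[gene.chrom])
                hi_i = max(hi_i, lo_i + 1)
            nfr.append((gene.chrom, int(lo_i), int(hi_i)))
    return sites, nfr


# ---------------------------------------------------------------------------
# divergence with planted outcomes

class _VariantAccumulator:
    """Merges per-strain substitutions into shared VCF-style records; the
    first writer of a position fixes its quality p-value."""

    def __init__(self):
        self.records: dict = {}

    def add(self, chrom, pos, ref, alt, strain, qual):
        key = (chrom, pos)
        rec = self.records.get(key)
        if rec is None:
            rec = {"ref": ref, "alts": {}, "qual": qual, "genotypes": {}}
            self.records[key] = rec
        if strain in rec["genotypes"]:
            return False
        rec["alts"].setdefault(alt, None)
        rec["genotypes"][strain] = alt
        return True

    def to_table(self) -> StrainVariantTable:
        rows = []
        for (chrom, pos), rec in sorted(self.records.items()):
            for strain, alt in sorted(rec["genotypes"].items()):
                rows.append(
                    {"strain_id": strain, "chrom": chrom, "pos": pos,
                     "ref": rec["ref"], "alt": alt, "qual_p": rec["qual"]}
                )
        return StrainVariantTable(pd.DataFrame(rows))


def _breaking_mutations(enc, pssm: PSSM, tau: float, allowed) -> list | None:
    """Greedy substitutions (position, new base code) driving the strength
    below `tau`; None when infeasible within the allowed positions."""
    lo = pssm.log_odds
    enc = enc.copy()
    idx = np.arange(pssm.length)
    score = lo[idx, enc].sum()
    target = tau * pssm.max_score
    muts = []
    candidates = sorted(allowed)
    while score >= target:
        best = None
        for i in candidates:
            drop = lo[i, enc[i]] - lo[i, :4].min()
            if drop > 0 and (best is None or drop > best[1]):
                best = (i, drop)
        if best is None:
            return None
        i = best[0]
        new = int(lo[i, :4].argmin())
        score += lo[i, new] - lo[i, enc[i]]
        enc[i] = new
        muts.append((i, new))
        candidates.remove(i)
    return muts


def _motif_to_genomic(site: BindingSite, i: int) -> int:
    return site.start + i if site.strand == "+" else site.end - 1 - i


def _passing_quality(rng) -> float:
    return float(10.0 ** -rng.uniform(4, 8))


def _failing_quality(rng) -> float:
    return float(rng.uniform(2e-3, 0.3))


def simulate_divergence(
    cfg: SimulationConfig,
    bundle: ReferenceBundle,
    rng: np.random.Generator,
) -> tuple[ReferenceBundle, pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw per-site conservation outcomes from the planted logistic model
    and realize them as strain variants and species sequences.

    Returns (completed bundle, truth table, gains truth, per-assignment
    feature rows, site-level design matrix).
    """
    thr = cfg.thresholds
    tau = thr.tau
    strain_ids = [f"strain{j + 1:02d}" for j in range(cfg.n_strains)]
    species_ids = [f"species{j + 1}" for j in range(cfg.n_species)]
    bundle.strain_ids = strain_ids
    bundle.species_ids = species_ids

    features = annotate_bundle(bundle)
    # one truth row per site: its nearest assignment
    site_feats = (
        features.sort_values(["site_id", "distance", "gene_id"], kind="stable")
        .drop_duplicates("site_id")
        .reset_index(drop=True)
    )
    terms = im.DEFAULT_TERMS + ["emap_partner"]
    # constant columns are kept: a planted coefficient on a feature absent
    # from a particular draw simply contributes nothing
    X, _tm = im.build_design_matrix(site_feats, terms, drop_constant=False)
    unknown = set(cfg.beta_true) - set(X.columns)
    if unknown:
        raise ValueError(f"beta_true references unknown features: {sorted(unknown)}")
    eta = np.zeros(len(X))
    for name, b in cfg.beta_true.items():
        eta += b * X[name].to_numpy()
    p_within = 1.0 / (1.0 + np.exp(-(cfg.intercept_within + eta)))
    p_between = 1.0 / (1.0 + np.exp(-(cfg.intercept_between + eta)))
    within_true = rng.random(len(X)) < p_within
    between_true = rng.random(len(X)) < p_between

    site_by_id = {s.site_id: s for s in bundle.sites}
    sites_ordered = [site_by_id[sid] for sid in site_feats["site_id"]]

    # positions covered by more than one site body: mutations there would
    # couple the outcomes of overlapping sites, so they are avoided
    cover = {c: np.zeros(n, dtype=np.int16) for c, n in bundle.chrom_lengths.items()}
    for s in bundle.sites:
        cover[s.chrom][s.start:s.end] += 1

    acc = _VariantAccumulator()
    genome = bundle.genome
    n_flipped = 0
    species_seqs: dict = {}
    n_species_conserved = np.zeros(len(X), dtype=int)
    n_strains_broken = np.zeros(len(X), dtype=int)

    for k, site in enumerate(sites_ordered):
        pssm = bundle.pssms[site.tf_id]
        enc_ref = encode_sequence(site.seq)
        nongap = [i for i in range(site.length) if i not in pssm.gap_positions]
        unshared = [
            i for i in range(site.length)
            if cover[site.chrom][_motif_to_genomic(site, i)] == 1
        ]
        allowed_break = sorted(set(nongap) & set(unshared))

        # --- within species -------------------------------------------------
        if not within_true[k]:
            muts = _breaking_mutations(enc_ref, pssm, tau, allowed_break)
            if muts is None:
                within_true[k] = True  # unrealizable under overlap constraints
                n_flipped += 1
            else:
                nb = int(min(rng.geometric(0.5), 3, cfg.n_strains))
                broken = rng.choice(cfg.n_strains, size=nb, replace=False)
                n_strains_broken[k] = nb
                qual = _passing_quality(rng)
                for i, new in muts:
                    gpos = _motif_to_genomic(site, i)
                    ref_b = genome[site.chrom][gpos]
                    alt_code = new if site.strand == "+" else int(_COMP[new])
                    for sj in sorted(broken):
                        acc.add(site.chrom, gpos, ref_b, BASES[alt_code],
                                strain_ids[sj], qual)
        if within_true[k]:
            u = rng.random()
            if u < cfg.benign_site_fraction and unshared:
                lo = pssm.log_odds
                for _ in range(10):
                    i = int(rng.choice(unshared))
                    new = int(rng.integers(0, 4))
                    if new == enc_ref[i]:
                        continue
                    delta = lo[i, new] - lo[i, enc_ref[i]]
                    if (lo[np.arange(site.length), enc_ref].sum() + delta
                            >= tau * pssm.max_score):
                        gpos = _motif_to_genomic(site, i)
                        alt_code = new if site.strand == "+" else int(_COMP[new])
                        acc.add(site.chrom, gpos, genome[site.chrom][gpos],
                                BASES[alt_code],
                                strain_ids[int(rng.integers(cfg.n_strains))],
                                _passing_quality(rng))
                        break
            elif u < cfg.benign_site_fraction + cfg.decoy_fraction:
                muts = _breaking_mutations(enc_ref, pssm, tau, allowed_break)
                if muts:
                    qual = _failing_quality(rng)
                    sj = int(rng.integers(cfg.n_strains))
                    for i, new in muts:
                        gpos = _motif_to_genomic(site, i)
                        alt_code = new if site.strand == "+" else int(_COMP[new])
                        acc.add(site.chrom, gpos, genome[site.chrom][gpos],
                                BASES[alt_code], strain_ids[sj], qual)

        # --- between species ------------------------------------------------
        present = [
            sp for sp in species_ids
            if rng.random() >= cfg.missing_species_fraction
        ]
        if between_true[k] and len(present) < 2:
            present = list(species_ids)
        if between_true[k]:
            nc = int(rng.integers(2, len(present) + 1))
        else:
            nc = int(rng.integers(0, 2))
            nc = min(nc, len(present))
        conserved_sp = list(rng.permutation(present))
        n_species_conserved[k] = nc
        lo = pssm.log_odds
        idx = np.arange(site.length)
        for j, sp in enumerate(conserved_sp):
            enc = enc_ref.copy()
            score = lo[idx, enc].sum()
            if j < nc:
                # retained copy: benign drift only
                for _ in range(int(rng.poisson(site.length * cfg.species_benign_rate))):
                    i = int(rng.integers(site.length))
                    new = int(rng.integers(0, 4))
                    d = lo[i, new] - lo[i, enc[i]]
                    if score + d >= tau * pssm.max_score:
                        score += d
                        enc[i] = new
            else:
                muts = _breaking_mutations(enc, pssm, tau, nongap)
                for i, new in muts:
                    enc[i] = new
                score = lo[idx, enc].sum()
                for _ in range(int(rng.poisson(site.length * 0.02))):
                    i = int(rng.integers(site.length))
                    new = int(rng.integers(0, 4))
                    d = lo[i, new] - lo[i, enc[i]]
                    if score + d < tau * pssm.max_score:
                        score += d
                        enc[i] = new
            species_seqs[(site.site_id, sp)] = "".join(BASES[b] for b in enc)

    if n_flipped:
        logger.warning(
            "%d within-species outcomes flipped: unrealizable under "
            "overlap constraints", n_flipped
        )

    # --- gained (turnover) sites in strain promoters ------------------------
    occupied = {c: np.zeros(n, dtype=bool) for c, n in bundle.chrom_lengths.items()}
    for s in bundle.sites:
        occupied[s.chrom][s.start:s.end] = True
        if s.strand == "+":
            occupied[s.chrom][s.end:min(s.end + thr.flank_bp, bundle.chrom_lengths[s.chrom])] = True
        else:
            occupied[s.chrom][max(s.start - thr.flank_bp, 0):s.start] = True
    tf_ids = sorted(bundle.pssms)
    gain_rows = []
    for gene in bundle.genes:
        if rng.random() >= cfg.gain_fraction:
            continue
        tf_id = tf_ids[int(rng.integers(len(tf_ids)))]
        pssm = bundle.pssms[tf_id]
        L = pssm.length
        p_lo, p_hi = _promoter_interval(gene, thr.promoter_bp,
                                        bundle.chrom_lengths[gene.chrom])
        if p_hi - p_lo < L:
            continue
        strain = strain_ids[int(rng.integers(cfg.n_strains))]
        lo = pssm.log_odds
        idx = np.arange(L)
        for _try in range(20):
            start = int(rng.integers(p_lo, p_hi - L + 1))
            if occupied[gene.chrom][start:start + L].any():
                continue
            win = encode_sequence(genome[gene.chrom][start:start + L])
            s_fwd = lo[idx, win].sum() / pssm.max_score
            s_rev = lo[idx, _COMP[win][::-1]].sum() / pssm.max_score
            if s_fwd >= tau or s_rev >= tau:
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            cons = lo[:, :4].argmax(axis=1).astype(np.uint8)
            planted = cons if strand == "+" else _COMP[cons][::-1]
            qual = _passing_quality(rng)
            for i in range(L):
                if planted[i] != win[i]:
                    acc.add(gene.chrom, start + i,
                            genome[gene.chrom][start + i],
                            BASES[planted[i]], strain, qual)
            # reserve the window so later gains cannot partially overwrite it
            occupied[gene.chrom][start:start + L] = True
            gain_rows.append(
                {"gene_id": gene.gene_id, "tf_id": tf_id, "strain_id": strain,
                 "chrom": gene.chrom, "start": start, "strand": strand}
            )
            break

    # --- background SNPs outside binding sites ------------------------------
    for chrom in sorted(bundle.genome):
        free = np.nonzero(cover[chrom] == 0)[0]
        seq = bundle.genome[chrom]
        for strain in strain_ids:
            n_mut = rng.binomial(len(free), cfg.background_mutation_rate)
            if n_mut == 0:
                continue
            positions = rng.choice(free, size=n_mut, replace=False)
            for pos in sorted(int(p) for p in positions):
                ref_b = seq[pos]
                alt = BASES[(encode_sequence(ref_b)[0] + int(rng.integers(1, 4))) % 4]
                qual = (
                    _failing_quality(rng)
                    if rng.random() < cfg.quality_fail_fraction
                    else _passing_quality(rng)
                )
                acc.add(chrom, pos, ref_b, alt, strain, qual)

    bundle.variants = acc.to_table()
    bundle.species_sequences = species_seqs

    truth = site_feats.copy()
    truth["eta"] = eta
    truth["p_within"] = p_within
    truth["p_between"] = p_between
    truth["within_true"] = within_true.astype(int)
    truth["between_true"] = between_true.astype(int)
    truth["n_species_conserved"] = n_species_conserved
    truth["n_strains_broken"] = n_strains_broken
    gains = pd.DataFrame(
        gain_rows,
        columns=["gene_id", "tf_id", "strain_id", "chrom", "start", "strand"],
    )
    return bundle, truth, gains, features, X


# ---------------------------------------------------------------------------
# top level

def generate_bundle(
    cfg: SimulationConfig | None = None, seed: int = 0
) -> SimulationResult:
    """Generate a full reference bundle plus its truth table."""
    cfg = cfg or SimulationConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    pssms = generate_pssm_set(cfg, rng)
    genome_arrays, genes = generate_genome_and_genes(cfg, rng)
    sites, nfr = plant_binding_sites(cfg, genome_arrays, genes, pssms, rng)
    genome = {c: "".join(BASES[b] for b in a) for c, a in sorted(genome_arrays.items())}

    # TF attribute table and E-MAP scores
    tf_ids = sorted(pssms)
    hier = list(rng.choice(["top", "core", "bottom"], size=len(tf_ids),
                           p=cfg.hierarchy_proportions))
    for i in range(len(tf_ids)):
        if rng.random() < cfg.fraction_unassigned_hierarchy:
            hier[i] = "unassigned"
    tf_table = pd.DataFrame(
        {
            "tf_id": tf_ids,
            "essential": rng.random(len(tf_ids)) < cfg.fraction_essential_tfs,
            "hierarchy": hier,
        }
    )
    emap = {}
    n_pairs = min(cfg.n_emap_pairs, len(tf_ids) * (len(tf_ids) - 1) // 2)
    forced_negative = 5
    while len(emap) < n_pairs:
        a, b = rng.choice(len(tf_ids), size=2, replace=False)
        key = frozenset((tf_ids[a], tf_ids[b]))
        if key in emap:
            continue
        if len(emap) < forced_negative:
            emap[key] = float(rng.uniform(-6, -3.5))
        else:
            emap[key] = float(rng.normal(-1.0, 2.0))

    bundle = ReferenceBundle(
        genome=genome, genes=genes, sites=sites, pssms=pssms,
        variants=StrainVariantTable(), strain_ids=[], species_ids=[],
        species_sequences={}, nfr_intervals=nfr, tf_table=tf_table,
        emap=emap, thresholds=cfg.thresholds,
    )
    bundle, truth, gains, features, X = simulate_divergence(cfg, bundle, rng)
    bundle.validate()
    logger.info(
        "simulated bundle: %d sites, %d variant records, within %.3f, "
        "between %.3f", len(sites), len(bundle.variants),
        truth["within_true"].mean(), truth["between_true"].mean(),
    )
    return SimulationResult(cfg, bundle, truth, gains, features, X)


def write_simulation(result: SimulationResult, outdir) -> Path:
    """Write the bundle files plus truth_table.tsv and gains_truth.tsv."""
    outdir = Path(outdir)
    manifest = write_reference_bundle(result.bundle, outdir)
    write_tsv_table(result.truth, outdir / "truth_table.tsv")
    write_tsv_table(
        result.gains if len(result.gains) else
        pd.DataFrame(columns=result.gains.columns),
        outdir / "gains_truth.tsv",
    )
    write_tsv_table(result.features, outdir / "features_truth.tsv")
    return manifest
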