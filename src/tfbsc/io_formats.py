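"""Readers and writers for the files the pipeline consumes and produces.

Coordinate conventions are fixed here once: everything is 0-based,
half-open internally (BED native).  The gene table carries 1-based TSS
positions on disk and is converted on load.  The VCF subset consumed is
CHROM/POS/REF/ALT/QUAL plus per-strain genotype columns; QUAL carries the
sequence-quality confidence p-value used by the strain SNP filter.
Insertion/deletion records are skipped on load (with a counter), since the
analysis considers single-nucleotide variants only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motif_scoring import PSSM, reverse_complement

logger = logging.getLogger("tfbsc")

__all__ = [
    "Thresholds",
    "GeneAnnotation",
    "BindingSite",
    "StrainVariantTable",
    "ReferenceBundle",
    "BundleValidationError",
    "parse_pssm_file",
    "write_pssm_file",
    "read_fasta",
    "write_fasta",
    "read_gene_table",
    "write_gene_table",
    "read_sites_bed",
    "write_sites_bed",
    "read_bed3",
    "write_bed3",
    "read_variants_vcf",
    "write_variants_vcf",
    "read_species_sequences",
    "write_species_sequences",
    "read_tf_table",
    "read_emap",
    "write_tsv_table",
    "read_tsv_table",
    "load_reference_bundle",
    "write_reference_bundle",
]

ESSENTIAL_LEVELS = ("essential", "slow_growth", "none")
REGULATOR_CLASSES = ("tf", "non_tf_regulator", "none")
HIERARCHY_LEVELS = ("top", "core", "bottom", "unassigned")


class BundleValidationError(ValueError):
    """Cross-reference validation of a loaded reference bundle failed."""


@dataclass(frozen=True)
class Thresholds:
    """All analysis cut-offs, with the study defaults."""

    tau: float = 0.6                 # strength threshold for functional conservation
    quality_p: float = 1e-3          # strain SNP quality: keep records with p < this
    subtelomere_bp: int = 40_000     # distance to a chromosome end
    nfr_window_bp: int = 150         # window before the TSS for NFR overlap
    promoter_bp: int = 1000          # promoter assignment range upstream of a TSS
    flank_bp: int = 10               # downstream flanking-divergence window
    pssm_similarity_r: float = 0.7   # in-vitro confirmed motif cut-off
    emap_negative: float = -3.0      # negative genetic interaction cut-off
    alpha: float = 0.05              # stepwise / significance level


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    chrom: str
    tss: int          # 0-based position of the transcription start site
    strand: str       # '+' or '-'
    essential: str = "none"
    overexpression_harmful: bool = False
    regulator_class: str = "none"
    hierarchy: str = "unassigned"

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        if self.essential not in ESSENTIAL_LEVELS:
            raise ValueError(f"bad essential level {self.essential!r}")
        if self.regulator_class not in REGULATOR_CLASSES:
            raise ValueError(f"bad regulator class {self.regulator_class!r}")
        if self.hierarchy not in HIERARCHY_LEVELS:
            raise ValueError(f"bad hierarchy {self.hierarchy!r}")
        if self.hierarchy != "unassigned" and self.regulator_class != "tf":
            raise ValueError(
                f"{self.gene_id}: hierarchy assigned to a non-TF gene"
            )


@dataclass(frozen=True)
class BindingSite:
    """A genomic binding-site interval with its annotated-strand sequence."""

    site_id: str
    chrom: str
    start: int
    end: int
    tf_id: str
    strand: str
    seq: str = ""     # reference sequence, oriented along `strand`

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


class StrainVariantTable:
    """Single-nucleotide variants of a strain panel, indexed by position.

    Wraps a DataFrame with columns ``strain_id, chrom, pos, ref, alt,
    qual_p`` (pos 0-based).  ``n_indels_skipped`` counts indel records
    dropped at load time.
    """

    COLUMNS = ["strain_id", "chrom", "pos", "ref", "alt", "qual_p"]

    def __init__(self, df: pd.DataFrame | None = None, n_indels_skipped: int = 0):
        if df is None or len(df) == 0:
            df = pd.DataFrame(columns=self.COLUMNS)
        df = df[self.COLUMNS].sort_values(["chrom", "pos", "strain_id"], kind="stable")
        self.df = df.reset_index(drop=True)
        self.n_indels_skipped = n_indels_skipped
        self._by_chrom = {}
        for chrom, sub in self.df.groupby("chrom", sort=False):
            sub = sub.reset_index(drop=True)
            self._by_chrom[chrom] = (sub["pos"].to_numpy(), sub)

    def __len__(self):
        return len(self.df)

    @property
    def strain_ids(self) -> list[str]:
        return sorted(self.df["strain_id"].unique())

    def in_interval(
        self,
        chrom: str,
        start: int,
        end: int,
        max_quality_p: float | None = None,
    ) -> pd.DataFrame:
        """Variant records with start <= pos < end, optionally quality-filtered."""
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return self.df.iloc[0:0]
        positions, sub = entry
        lo, hi = np.searchsorted(positions, [start, end])
        out = sub.iloc[lo:hi]
        if max_quality_p is not None:
            out = out[out["qual_p"] < max_quality_p]
        return out


@dataclass
class ReferenceBundle:
    """Everything the pipeline needs, cross-validated on load."""

    genome: dict
    genes: list
    sites: list
    pssms: dict
    variants: StrainVariantTable
    strain_ids: list
    species_ids: list
    species_sequences: dict       # (site_id, species_id) -> sequence
    nfr_intervals: list           # (chrom, start, end)
    tf_table: pd.DataFrame        # tf_id, essential, hierarchy
    emap: dict                    # frozenset({tf_a, tf_b}) -> score
    thresholds: Thresholds = field(default_factory=Thresholds)

    @property
    def chrom_lengths(self) -> dict:
        return {c: len(s) for c, s in self.genome.items()}

    def validate(self):
        lengths = self.chrom_lengths
        tf_missing = sorted(
            {s.tf_id for s in self.sites if s.tf_id not in self.pssms}
        )
        if tf_missing:
            raise BundleValidationError(
                f"sites reference TFs without a PSSM: {', '.join(tf_missing)}"
            )
        for s in self.sites:
            if s.chrom not in lengths:
                raise BundleValidationError(
                    f"site {s.site_id} on unknown chromosome {s.chrom}"
                )
            if not (0 <= s.start < s.end <= lengths[s.chrom]):
                raise BundleValidationError(
                    f"site {s.site_id} outside chromosome bounds"
                )
            if len(s.seq) != s.end - s.start:
                raise BundleValidationError(
                    f"site {s.site_id} sequence length != end - start"
                )
        for g in self.genes:
            if g.chrom not in lengths or not (0 <= g.tss < lengths[g.chrom]):
                raise BundleValidationError(
                    f"gene {g.gene_id} TSS outside chromosome bounds"
                )
        site_len = {s.site_id: s.length for s in self.sites}
        for (site_id, sp), seq in self.species_sequences.items():
            if site_id in site_len and len(seq) != site_len[site_id]:
                raise BundleValidationError(
                    f"species sequence for {site_id}/{sp} has wrong length"
                )


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> dict:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: dict, path):
    records = [
        SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# PSSM plain-text format
#
#   >tf_id N [gaps=i,j,...]
#   p_A p_C p_G p_T        (N rows, A,C,G,T order)
#   background p_A p_C p_G p_T   (optional)

def parse_pssm_file(path) -> dict:
    pssms = {}
    header = None
    rows: list = []
    background = None
    gaps: frozenset = frozenset()

    def _finish(lineno):
        nonlocal header, rows, background, gaps
        if header is None:
            return
        tf_id, n = header
        if len(rows) != n:
            raise ValueError(
                f"{path}:{lineno}: PSSM {tf_id} declares {n} rows, found {len(rows)}"
            )
        probs = np.array(rows, dtype=float)
        sums = probs.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            logger.warning("PSSM %s rows renormalized to sum to 1", tf_id)
            probs = probs / sums[:, None]
        bg = np.full(4, 0.25) if background is None else np.asarray(background)
        pssms[tf_id] = PSSM(tf_id, probs, bg, gaps)
        header, rows, background, gaps = None, [], None, frozenset()

    lineno = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                _finish(lineno)
                parts = line[1:].split()
                if len(parts) < 2:
                    raise ValueError(f"{path}:{lineno}: malformed PSSM header")
                tf_id, n = parts[0], int(parts[1])
                if n < 1:
                    raise ValueError(f"{path}:{lineno}: motif length must be >= 1")
                gaps = frozenset()
                for extra in parts[2:]:
                    if extra.startswith("gaps="):
                        gaps = frozenset(
                            int(i) for i in extra[5:].split(",") if i != ""
                        )
                header = (tf_id, n)
            elif line.startswith("background"):
                background = [float(x) for x in line.split()[1:]]
            else:
                vals = [float(x) for x in line.split()]
                if len(vals) != 4:
                    raise ValueError(
                        f"{path}:{lineno}: expected 4 probabilities, got {len(vals)}"
                    )
                if any(v < 0 for v in vals):
                    raise ValueError(f"{path}:{lineno}: negative probability")
                rows.append(vals)
        _finish(lineno)
    return pssms


def write_pssm_file(pssms: dict, path):
    with open(path, "w") as fh:
        for tf_id in sorted(pssms):
            p = pssms[tf_id]
            gap = (
                " gaps=" + ",".join(str(i) for i in sorted(p.gap_positions))
                if p.gap_positions
                else ""
            )
            fh.write(f">{tf_id} {p.length}{gap}\n")
            for row in p.probs:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("background " + " ".join(f"{v:.6f}" for v in p.background) + "\n")


# ---------------------------------------------------------------------------
# Gene table (TSV; TSS is 1-based on disk)

GENE_COLUMNS = [
    "gene_id", "chrom", "tss", "strand", "essential",
    "overexpression_harmful", "regulator_class", "hierarchy",
]


def read_gene_table(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype={"tss": int})
    genes = []
    for row in df.itertuples(index=False):
        genes.append(
            GeneAnnotation(
                gene_id=row.gene_id,
                chrom=row.chrom,
                tss=int(row.tss) - 1,
                strand=row.strand,
                essential=row.essential,
                overexpression_harmful=bool(int(row.overexpression_harmful)),
                regulator_class=row.regulator_class,
                hierarchy=row.hierarchy,
            )
        )
    return genes


def write_gene_table(genes: list, path):
    rows = [
        {
            "gene_id": g.gene_id, "chrom": g.chrom, "tss": g.tss + 1,
            "strand": g.strand, "essential": g.essential,
            "overexpression_harmful": int(g.overexpression_harmful),
            "regulator_class": g.regulator_class, "hierarchy": g.hierarchy,
        }
        for g in genes
    ]
    pd.DataFrame(rows, columns=GENE_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED

def read_sites_bed(path, genome: dict) -> list:
    sites = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, end, name, _score, strand = line.split("\t")[:6]
            site_id, tf_id = name.split("|")
            start, end = int(start), int(end)
            if chrom not in genome:
                raise BundleValidationError(
                    f"site {site_id} on chromosome {chrom} absent from genome"
                )
            seq = genome[chrom][start:end]
            if strand == "-":
                seq = reverse_complement(seq)
            sites.append(BindingSite(site_id, chrom, start, end, tf_id, strand, seq))
    return sites


def write_sites_bed(sites: list, path):
    with open(path, "w") as fh:
        for s in sorted(sites, key=lambda s: (s.chrom, s.start, s.site_id)):
            fh.write(
                f"{s.chrom}\t{s.start}\t{s.end}\t{s.site_id}|{s.tf_id}\t0\t{s.strand}\n"
            )


def read_bed3(path) -> list:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, end = line.split("\t")[:3]
            out.append((chrom, int(start), int(end)))
    return out


def write_bed3(intervals: list, path):
    with open(path, "w") as fh:
        for chrom, start, end in sorted(intervals):
            fh.write(f"{chrom}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# VCF (minimal SNV subset; QUAL = sequence-quality confidence p-value)

def read_variants_vcf(path, genome: dict | None = None) -> tuple:
    """Load strain SNVs; returns (StrainVariantTable, strain_ids)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    strains = list(vcf.samples)
    records = []
    n_indels = 0
    for var in vcf:
        alts = var.ALT
        if len(var.REF) != 1 or any(len(a) != 1 or a not in "ACGT" for a in alts):
            n_indels += 1
            continue
        pos = var.POS - 1
        if genome is not None:
            ref_base = genome[var.CHROM][pos]
            if ref_base != var.REF:
                raise BundleValidationError(
                    f"variant REF mismatch at {var.CHROM}:{var.POS} "
                    f"(VCF {var.REF}, genome {ref_base})"
                )
        qual = 0.0 if var.QUAL is None else float(var.QUAL)
        for strain, gt in zip(strains, var.genotypes):
            allele = gt[0]
            if allele is None or allele <= 0:
                continue  # reference or no call: assume reference
            records.append(
                {
                    "strain_id": strain, "chrom": var.CHROM, "pos": pos,
                    "ref": var.REF, "alt": alts[allele - 1], "qual_p": qual,
                }
            )
    table = StrainVariantTable(pd.DataFrame(records), n_indels_skipped=n_indels)
    if n_indels:
        logger.info("skipped %d indel records in %s", n_indels, path)
    return table, strains


def write_variants_vcf(table: StrainVariantTable, strain_ids: list, genome: dict, path):
    df = table.df
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=tfbsc\n")
        fh.write(
            "##tfbsc_qual_semantics=sequence-quality confidence p-value; "
            "records with p<1e-3 pass the strain SNP filter\n"
        )
        for chrom in sorted(genome):
            fh.write(f"##contig=<ID={chrom},length={len(genome[chrom])}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(strain_ids) + "\n"
        )
        for (chrom, pos), grp in df.groupby(["chrom", "pos"], sort=True):
            ref = grp["ref"].iloc[0]
            alts = list(dict.fromkeys(grp["alt"]))
            qual = grp["qual_p"].iloc[0]
            allele = {
                row.strain_id: alts.index(row.alt) + 1
                for row in grp.itertuples(index=False)
            }
            gts = "\t".join(
                f"{allele.get(s, 0)}/{allele.get(s, 0)}" for s in strain_ids
            )
            fh.write(
                f"{chrom}\t{pos + 1}\t.\t{ref}\t{','.join(alts)}\t{qual:.3g}"
                f"\t.\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# TSV tables

def read_species_sequences(path) -> tuple:
    df = pd.read_csv(path, sep="\t", dtype=str)
    seqs = {}
    for row in df.itertuples(index=False):
        if isinstance(row.sequence, str) and row.sequence not in ("", "NA"):
            seqs[(row.site_id, row.species_id)] = row.sequence
    species = sorted(df["species_id"].unique())
    return seqs, species


def write_species_sequences(seqs: dict, path):
    rows = [
        {"site_id": sid, "species_id": sp, "sequence": seq}
        for (sid, sp), seq in sorted(seqs.items())
    ]
    pd.DataFrame(rows, columns=["site_id", "species_id", "sequence"]).to_csv(
        path, sep="\t", index=False
    )


def read_tf_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"tf_id": str})
    df["essential"] = df["essential"].astype(int).astype(bool)
    bad = ~df["hierarchy"].isin(HIERARCHY_LEVELS)
    if bad.any():
        raise ValueError(f"bad hierarchy levels: {df.loc[bad, 'hierarchy'].unique()}")
    return df


def read_emap(path) -> dict:
    df = pd.read_csv(path, sep="\t")
    emap = {}
    for row in df.itertuples(index=False):
        key = frozenset((row.tf_a, row.tf_b))
        score = float(row.score)
        emap[key] = min(score, emap.get(key, np.inf))
    return emap


def write_emap(emap: dict, path):
    rows = []
    for key in sorted(emap, key=sorted):
        pair = sorted(key)
        a, b = (pair[0], pair[0]) if len(pair) == 1 else pair
        rows.append({"tf_a": a, "tf_b": b, "score": emap[key]})
    pd.DataFrame(rows, columns=["tf_a", "tf_b", "score"]).to_csv(
        path, sep="\t", index=False
    )


def write_tsv_table(records, path):
    """Write uniform records to TSV; missing values become the literal 'NA'."""
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        records = list(records)
        if records:
            keys = list(records[0].keys())
            for i, rec in enumerate(records):
                if list(rec.keys()) != keys:
                    raise ValueError(f"record {i} fields differ from header")
            df = pd.DataFrame(records, columns=keys)
        else:
            raise ValueError("cannot infer a header from an empty record list")
    if df.columns.empty:
        raise ValueError("table must have a non-empty header")
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_tsv_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)


# ---------------------------------------------------------------------------
# Bundle manifest

BUNDLE_FILES = {
    "genome": "genome.fa",
    "genes": "genes.tsv",
    "sites": "sites.bed",
    "pssms": "pssms.txt",
    "variants": "variants.vcf",
    "species_sequences": "species_sequences.tsv",
    "nfr": "nfr.bed",
    "tfs": "tfs.tsv",
    "emap": "emap.tsv",
}


def load_reference_bundle(config_path) -> ReferenceBundle:
    """Load and cross-validate a complete input bundle from its manifest."""
    config_path = Path(config_path)
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    base = config_path.parent
    files = {k: base / v for k, v in cfg.get("files", {}).items()}
    thr = Thresholds(**cfg.get("thresholds", {}))

    genome = read_fasta(files["genome"])
    genes = read_gene_table(files["genes"])
    sites = read_sites_bed(files["sites"], genome)
    pssms = parse_pssm_file(files["pssms"])
    variants, strain_ids = read_variants_vcf(files["variants"], genome)
    species_sequences, species_ids = read_species_sequences(
        files["species_sequences"]
    )
    if "species" in cfg:
        species_ids = list(cfg["species"])
    nfr = read_bed3(files["nfr"])
    tf_table = read_tf_table(files["tfs"])
    emap = read_emap(files["emap"])

    bundle = ReferenceBundle(
        genome=genome, genes=genes, sites=sites, pssms=pssms,
        variants=variants, strain_ids=strain_ids, species_ids=species_ids,
        species_sequences=species_sequences, nfr_intervals=nfr,
        tf_table=tf_table, emap=emap, thresholds=thr,
    )
    bundle.validate()
    logger.info(
        "loaded bundle: %d chromosomes, %d genes, %d sites, %d PSSMs, "
        "%d variant records (%d indels skipped), %d strains, %d species",
        len(genome), len(genes), len(sites), len(pssms), len(variants),
        variants.n_indels_skipped, len(strain_ids), len(species_ids),
    )
    return bundle


def write_reference_bundle(bundle: ReferenceBundle, outdir) -> Path:
    """Write a bundle to a directory; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(bundle.genome, outdir / BUNDLE_FILES["genome"])
    write_gene_table(bundle.genes, outdir / BUNDLE_FILES["genes"])
    write_sites_bed(bundle.sites, outdir / BUNDLE_FILES["sites"])
    write_pssm_file(bundle.pssms, outdir / BUNDLE_FILES["pssms"])
    write_variants_vcf(
        bundle.variants, bundle.strain_ids, bundle.genome,
        outdir / BUNDLE_FILES["variants"],
    )
    write_species_sequences(
        bundle.species_sequences, outdir / BUNDLE_FILES["species_sequences"]
    )
    write_bed3(bundle.nfr_intervals, outdir / BUNDLE_FILES["nfr"])
    bundle.tf_table.assign(essential=bundle.tf_table["essential"].astype(int)).to_csv(
        outdir / BUNDLE_FILES["tfs"], sep="\t", index=False
    )
    write_emap(bundle.emap, outdir / BUNDLE_FILES["emap"])
    manifest = outdir / "config.yaml"
    with open(manifest, "w") as fh:
        yaml.safe_dump(
            {
                "files": BUNDLE_FILES,
                "thresholds": {
                    k: getattr(bundle.thresholds, k)
                    for k in Thresholds.__dataclass_fields__
                },
                "species": list(bundle.species_ids),
            },
            fh,
        )
    return manifest
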