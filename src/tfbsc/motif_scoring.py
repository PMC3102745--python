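"""PSSM log-odds scoring of transcription-factor binding sites.

A binding site is scored against a position-specific scoring matrix (PSSM)
as the sum over motif positions of ``log2(p_i(base) / b(base))``, where
``p_i`` is the per-position base likelihood and ``b`` the background base
frequency.  The *strength* (optimality) of a site is this raw score divided
by the maximum score attainable for the matrix, and a site is called
functionally conserved when its strength is at least a threshold ``tau``
(0.6 by default, closed boundary).  Gap positions of a motif carry no
information and contribute nothing to the score; an ``N`` base likewise
contributes zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable

import numpy as np

__all__ = [
    "PSSM",
    "SiteScore",
    "DegeneratePSSMError",
    "encode_sequence",
    "reverse_complement",
    "score_sequence",
    "strength",
    "is_functionally_conserved",
    "scan_promoter",
    "pssm_similarity",
]

DEFAULT_TAU = 0.6
BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
# A<->T, C<->G; N maps to itself.
_COMPLEMENT_IDX = np.array([3, 2, 1, 0, 4], dtype=np.uint8)
_ENCODE_TABLE = np.full(256, 255, dtype=np.uint8)
for _b, _i in BASE_INDEX.items():
    _ENCODE_TABLE[ord(_b)] = _i
    _ENCODE_TABLE[ord(_b.lower())] = _i
_ENCODE_TABLE[ord("N")] = 4
_ENCODE_TABLE[ord("n")] = 4
_COMPLEMENT_STR = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class DegeneratePSSMError(ValueError):
    """Raised when a PSSM has no positive maximum score to normalize by."""


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a DNA string into uint8 codes A=0, C=1, G=2, T=3, N=4."""
    enc = _ENCODE_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (enc == 255).any():
        bad = seq[int(np.argmax(enc == 255))]
        raise ValueError(f"invalid base {bad!r} in sequence")
    return enc


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT_STR)[::-1]


@dataclass(frozen=True)
class PSSM:
    """Per-position base likelihoods for a transcription factor.

    Parameters
    ----------
    tf_id : str
        Identifier of the transcription factor the matrix models.
    probs : ndarray, shape (N, 4)
        Likelihood of A, C, G, T at each motif position; rows sum to 1.
    background : ndarray, shape (4,)
        Background base frequencies (uniform by default).
    gap_positions : frozenset of int
        Motif positions that carry no binding information; they are
        excluded from scoring and from the maximum score.
    pseudocount : float
        Floor applied to ``probs`` before taking logs, preventing
        minus-infinity scores for bases never observed at a position.
    """

    tf_id: str
    probs: np.ndarray = field(compare=False)
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25), compare=False
    )
    gap_positions: frozenset = field(default_factory=frozenset)
    pseudocount: float = 1e-3

    def __post_init__(self):
        probs = np.asarray(self.probs, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "background", bg)
        object.__setattr__(self, "gap_positions", frozenset(self.gap_positions))
        if probs.ndim != 2 or probs.shape[1] != 4 or probs.shape[0] < 1:
            raise ValueError("PSSM probabilities must be a non-empty (N, 4) matrix")
        if (probs < 0).any():
            raise ValueError(f"negative probability in PSSM {self.tf_id}")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"PSSM {self.tf_id} rows do not sum to 1")
        if not np.isclose(bg.sum(), 1.0, atol=1e-6):
            raise ValueError("background frequencies must sum to 1")
        if not (0 < self.pseudocount <= 0.01):
            raise ValueError("pseudocount must lie in (0, 0.01]")
        if any(g < 0 or g >= probs.shape[0] for g in self.gap_positions):
            raise ValueError("gap position outside motif")

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    @cached_property
    def log_odds(self) -> np.ndarray:
        """(N, 5) log2 odds; column 4 (base N) and gap rows are zero."""
        lo = np.log2(np.maximum(self.probs, self.pseudocount) / self.background)
        if self.gap_positions:
            lo[sorted(self.gap_positions), :] = 0.0
        return np.hstack([lo, np.zeros((self.length, 1))])

    @cached_property
    def max_score(self) -> float:
        return float(self.log_odds[:, :4].max(axis=1).sum())

    @cached_property
    def consensus(self) -> str:
        """Highest-likelihood base at each position (gaps report 'A')."""
        return "".join(BASES[i] for i in self.log_odds[:, :4].argmax(axis=1))

    def information_content(self) -> float:
        """Total Shannon information (bits) over non-gap positions."""
        p = self.probs
        with np.errstate(divide="ignore", invalid="ignore"):
            ent = -np.where(p > 0, p * np.log2(p), 0.0).sum(axis=1)
        ic = 2.0 - ent
        keep = np.ones(self.length, dtype=bool)
        for g in self.gap_positions:
            keep[g] = False
        return float(ic[keep].sum())


@dataclass(frozen=True)
class SiteScore:
    site_id: str
    raw_score: float
    max_score: float
    strength: float
    conserved: bool


def score_sequence(seq: str, pssm: PSSM) -> float:
    """Sum of per-position log2 odds of `seq` under `pssm` (bits)."""
    if len(seq) != pssm.length:
        raise ValueError(
            f"sequence length {len(seq)} != motif length {pssm.length} "
            f"for {pssm.tf_id}"
        )
    enc = encode_sequence(seq)
    return float(pssm.log_odds[np.arange(pssm.length), enc].sum())


def strength(seq: str, pssm: PSSM) -> float:
    """Score normalized to the maximum possible score; consensus gives 1."""
    if pssm.max_score <= 0:
        raise DegeneratePSSMError(
            f"PSSM {pssm.tf_id} has non-positive maximum score"
        )
    return score_sequence(seq, pssm) / pssm.max_score


def is_functionally_conserved(seq: str, pssm: PSSM, tau: float = DEFAULT_TAU) -> bool:
    """True when the sequence retains at least `tau` of the maximum score."""
    return strength(seq, pssm) >= tau


def _window_scores(enc: np.ndarray, pssm: PSSM) -> np.ndarray:
    n = pssm.length
    windows = np.lib.stride_tricks.sliding_window_view(enc, n)
    return pssm.log_odds[np.arange(n)[None, :], windows].sum(axis=1)


def scan_promoter(
    seq: str, pssm: PSSM, tau: float = DEFAULT_TAU
) -> list[tuple[int, str, float]]:
    """All windows on either strand with strength >= tau.

    Returns ``(offset, strand, strength)`` tuples with offsets 0-based on
    the forward strand, sorted by offset ('+' before '-' at equal offset).
    """
    n = pssm.length
    if len(seq) < n:
        raise ValueError("promoter shorter than motif")
    if pssm.max_score <= 0:
        raise DegeneratePSSMError(f"PSSM {pssm.tf_id} has non-positive maximum score")
    enc = encode_sequence(seq)
    hits = []
    fwd = _window_scores(enc, pssm) / pssm.max_score
    for off in np.nonzero(fwd >= tau)[0]:
        hits.append((int(off), "+", float(fwd[off])))
    rc = _COMPLEMENT_IDX[enc][::-1]
    rev = _window_scores(rc, pssm) / pssm.max_score
    for off_rc in np.nonzero(rev >= tau)[0]:
        hits.append((len(seq) - n - int(off_rc), "-", float(rev[off_rc])))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def _revcomp_probs(p: np.ndarray) -> np.ndarray:
    return p[::-1, ::-1]


def pssm_similarity(a: PSSM, b: PSSM) -> float:
    """Maximum Pearson correlation of the two probability matrices.

    All ungapped offsets with at least ``min(Na, Nb) - 2`` (and >= 3)
    overlapping columns are considered, in both orientations of `b`
    (reverse complement included); the correlation is computed on the
    flattened overlapping columns.
    """
    pa, pb = a.probs, b.probs
    na, nb = pa.shape[0], pb.shape[0]
    min_overlap = max(min(na, nb) - 2, 3)
    if min(na, nb) < 3:
        raise ValueError("motifs too short to overlap by 3 columns")
    best = -np.inf
    for mat in (pb, _revcomp_probs(pb)):
        for shift in range(-(nb - min_overlap), na - min_overlap + 1):
            lo_a, hi_a = max(0, shift), min(na, shift + nb)
            if hi_a - lo_a < min_overlap:
                continue
            xa = pa[lo_a:hi_a].ravel()
            xb = mat[lo_a - shift : hi_a - shift].ravel()
            if xa.std() == 0 or xb.std() == 0:
                continue
            r = float(np.corrcoef(xa, xb)[0, 1])
            best = max(best, r)
    if not np.isfinite(best):
        raise ValueError("no alignment with enough overlapping columns")
    return best


def score_sites(
    sites: Iterable, pssms: dict, tau: float = DEFAULT_TAU
) -> list[SiteScore]:
    """Score annotated binding sites on their annotated strand."""
    out = []
    for site in sites:
        pssm = pssms[site.tf_id]
        raw = score_sequence(site.seq, pssm)
        st = raw / pssm.max_score
        out.append(SiteScore(site.site_id, raw, pssm.max_score, st, st >= tau))
    return out
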