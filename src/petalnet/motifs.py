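"""Position-weight-matrix promoter scanning with exact background p-values.

A :class:`PWM` is a probabilistic model of a transcription-factor binding
site over the DNA alphabet.  Windows of a promoter are scored with the
log-odds score (bits) against a background base composition, and each score
is assigned the exact probability that a random background window of the
same width scores at least as high.  That tail probability is computed by
dynamic programming on a discretized score lattice: per-column score
distributions are convolved, so no sampling is involved and the p-value is
exact up to the score discretization.

Promoters are the ``length`` bases upstream of a gene's annotated start
(2 kb by default), stored 5'->3' relative to the gene, i.e. reverse
complemented for minus-strand genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: width of one discretization bin of the score lattice, in bits
SCORE_BIN_BITS = 0.001


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PWM:
    """A position-weight matrix over (A, C, G, T) with a background model.

    ``probs`` has shape (4, w); every column sums to 1.  A pseudocount is
    added to each cell on construction (then columns are renormalized) so
    log-odds scores are finite even for 0/1 consensus matrices.
    """

    motif_id: str
    tf_family: str
    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[0] != 4:
            raise ValueError("probs must be a 4 x w matrix over (A,C,G,T)")
        if self.width < 4:
            raise ValueError("motif width must be >= 4")
        if np.any(self.probs < 0) or np.any(self.background <= 0):
            raise ValueError("probabilities must be non-negative, background positive")
        if not np.allclose(self.probs.sum(axis=0), 1.0, atol=1e-3):
            raise ValueError("each PWM column must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise ValueError("background must sum to 1")
        # pseudocount regularization, then renormalize columns
        self.probs = self.probs + self.pseudocount
        self.probs = self.probs / self.probs.sum(axis=0, keepdims=True)
        self._cache: dict = {}

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=0))

    def log_odds(self) -> np.ndarray:
        """Per-base, per-column log2(p / background) in bits (4 x w)."""
        return np.log2(self.probs / self.background[:, None])

    # -- discretized score lattice -------------------------------------------

    def _lattice(self) -> tuple[np.ndarray, int, np.ndarray]:
        """Integer per-column scores, their common offset, and the exact
        background distribution of the integer total score.

        Integer scores are ``round(bits / SCORE_BIN_BITS)`` per column; the
        distribution of their sum is obtained by convolving the per-column
        distributions under the background.  Cached per PWM.
        """
        if "lattice" in self._cache:
            return self._cache["lattice"]
        ints = np.round(self.log_odds() / SCORE_BIN_BITS).astype(np.int64)
        lo = ints.min(axis=0)  # per-column minimum
        dist = np.array([1.0])
        for c in range(self.width):
            col = np.zeros(ints[:, c].max() - lo[c] + 1)
            for b in range(4):
                col[ints[b, c] - lo[c]] += self.background[b]
            dist = np.convolve(dist, col)
        offset = int(lo.sum())  # integer score of dist[0]
        self._cache["lattice"] = (ints, offset, dist)
        return self._cache["lattice"]

    def score_distribution(self) -> tuple[np.ndarray, np.ndarray]:
        """(scores_bits, probabilities) of a background-distributed window."""
        _, offset, dist = self._lattice()
        scores = (offset + np.arange(dist.size)) * SCORE_BIN_BITS
        return scores, dist


def pwm_score(pwm: PWM, window: str) -> float:
    """Log-odds score of one window, in bits."""
    if len(window) != pwm.width:
        raise ValueError(f"window length {len(window)} != motif width {pwm.width}")
    lods = pwm.log_odds()
    try:
        idx = [_BASE_INDEX[b] for b in window.upper()]
    except KeyError as exc:
        raise ValueError(f"window contains non-ACGT base: {exc}") from exc
    return float(sum(lods[b, c] for c, b in enumerate(idx)))


def score_pvalue(pwm: PWM, score_bits: float) -> float:
    """P(background window score >= ``score_bits``), exact on the lattice."""
    _, offset, dist = pwm._lattice()
    k = int(np.round(score_bits / SCORE_BIN_BITS)) - offset
    if k <= 0:
        return 1.0
    if k >= dist.size:
        return 0.0
    return float(dist[k:].sum())


@dataclass
class BindingHit:
    """A located, scored, p-valued motif occurrence in a promoter."""

    gene_id: str
    motif_id: str
    strand: str
    offset: int
    score: float
    p_value: float


@dataclass
class PromoterSet:
    """gene_id -> promoter sequence (5'->3' relative to the gene)."""

    sequences: dict[str, str]
    truncated: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for gene, seq in self.sequences.items():
            bad = set(seq.upper()) - set("ACGTN")
            if bad:
                raise ValueError(f"promoter of {gene} has invalid characters {bad}")

    def __getitem__(self, gene: str) -> str:
        return self.sequences[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self.sequences

    def base_composition(self) -> np.ndarray:
        """Empirical (A, C, G, T) frequencies over all promoters (N ignored)."""
        counts = np.zeros(4)
        for seq in self.sequences.values():
            s = seq.upper()
            for i, b in enumerate(BASES):
                counts[i] += s.count(b)
        if counts.sum() == 0:
            return np.full(4, 0.25)
        return counts / counts.sum()


@dataclass(frozen=True)
class GeneFeature:
    """A gene location in annotation convention: 1-based inclusive coordinates."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str


def extract_promoters(
    genome: Mapping[str, str],
    features: Iterable[GeneFeature],
    length: int = 2000,
) -> PromoterSet:
    """Strand-aware upstream regions of ``length`` bases for every feature.

    For a plus-strand gene the promoter is the ``length`` bases ending
    immediately before the feature start; for a minus-strand gene, the
    ``length`` bases starting immediately after the feature end, reverse
    complemented.  Promoters truncated at a contig edge are flagged; genes
    whose promoter would be empty are skipped with a warning.
    """
    sequences: dict[str, str] = {}
    truncated: set[str] = set()
    for feat in features:
        if feat.contig not in genome:
            raise KeyError(f"unknown contig {feat.contig!r} for gene {feat.gene_id}")
        contig = genome[feat.contig].upper()
        if feat.strand == "+":
            hi = feat.start - 1            # 0-based exclusive end
            lo = max(0, hi - length)
            prom = contig[lo:hi]
        elif feat.strand == "-":
            lo = feat.end                  # 0-based inclusive start
            hi = min(len(contig), lo + length)
            prom = reverse_complement(contig[lo:hi])
        else:
            raise ValueError(f"bad strand {feat.strand!r} for {feat.gene_id}")
        if not prom:
            warnings.warn(f"gene {feat.gene_id}: empty promoter, skipped")
            continue
        if len(prom) < length:
            truncated.add(feat.gene_id)
        sequences[feat.gene_id] = prom
    return PromoterSet(sequences, truncated)


def _encode(seq: str) -> np.ndarray:
    """Sequence -> integer codes; N (or any non-ACGT) -> 4."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    codes = np.full(arr.size, 4, dtype=np.int64)
    for i, b in enumerate(BASES):
        codes[arr == ord(b)] = i
    return codes


def _strand_hits(
    pwm: PWM, codes: np.ndarray, strand: str, threshold: float, gene_id: str
) -> list[BindingHit]:
    w = pwm.width
    n = codes.size - w + 1
    if n <= 0:
        return []
    _, offset, dist = pwm._lattice()
    sf = np.concatenate([np.cumsum(dist[::-1])[::-1], [0.0]])  # sf[k] = P(>= offset+k)
    lods = pwm.log_odds()
    if strand == "-":
        lods = lods[::-1, ::-1]
    wins = np.lib.stride_tricks.sliding_window_view(codes, w)
    valid = ~(wins == 4).any(axis=1)
    cols = np.arange(w)
    hits: list[BindingHit] = []
    if valid.any():
        vi = np.nonzero(valid)[0]
        bits = lods[wins[vi], cols].sum(axis=1)
        k = np.clip(np.round(bits / SCORE_BIN_BITS).astype(np.int64) - offset, 0, dist.size)
        pvals = sf[k]
        keep = pvals <= threshold
        for pos, b, p in zip(vi[keep], bits[keep], pvals[keep]):
            hits.append(BindingHit(gene_id, pwm.motif_id, strand, int(pos), float(b), float(p)))
    return hits


def scan_promoter(
    pwm: PWM,
    promoter: str,
    threshold: float = 1e-4,
    gene_id: str = "",
) -> list[BindingHit]:
    """All windows on both strands with exact p-value <= ``threshold``.

    Hits are reported in ascending offset ('+' before '-' at equal offset);
    offsets are 0-based window starts on the promoter as given.  Windows
    containing N are skipped.  A promoter shorter than the motif yields an
    empty list.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    codes = _encode(promoter)
    hits = _strand_hits(pwm, codes, "+", threshold, gene_id) + _strand_hits(
        pwm, codes, "-", threshold, gene_id
    )
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def scan_promoter_set(
    pwms: Sequence[PWM],
    promoters: PromoterSet,
    threshold: float = 1e-4,
    genes: Iterable[str] | None = None,
) -> list[BindingHit]:
    """Scan every promoter (or the given genes) with every motif."""
    out: list[BindingHit] = []
    for gene in genes if genes is not None else promoters.sequences:
        for pwm in pwms:
            out.extend(scan_promoter(pwm, promoters[gene], threshold, gene_id=gene))
    return out
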