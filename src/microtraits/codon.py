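"""Codon usage bias: ENC, background-corrected ENC′, and the ΔENC′ estimator.

Wright's effective number of codons (ENC) measures how far the synonymous
codon usage of a gene set departs from uniform usage: 20 means a single codon
per amino acid, 61 means all synonymous codons used equally.  ENC′ replaces
Wright's homozygosity F with a chi-square deviation from the codon frequencies
expected under the background nucleotide composition, so that compositional
(mutational) bias is discounted and the residual signal reflects selection.

ΔENC′ = (ENC′_all − ENC′_rib) / ENC′_all compares the bias of ribosomal
protein genes (highly expressed under fast growth) against all coding
sequences of a genome; it is an empirical proxy for translational selection
strength and hence maximum growth rate, a copiotroph life-history trait.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Orf",
    "CodonCounts",
    "Background",
    "CodonBiasResult",
    "SYNONYMOUS_FAMILIES",
    "STOP_CODONS",
    "extract_orfs",
    "count_codons",
    "background_from_sequences",
    "enc",
    "enc_prime",
    "delta_enc_prime",
]

STOP_CODONS = ("TAA", "TAG", "TGA")

# Standard genetic code (translation table 1).  Met (ATG) and Trp (TGG) are
# nondegenerate and excluded; the three sixfold families (Leu, Ser, Arg) are
# kept whole rather than split 2+4.
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {
    "Phe": ("TTT", "TTC"),
    "Tyr": ("TAT", "TAC"),
    "Cys": ("TGT", "TGC"),
    "His": ("CAT", "CAC"),
    "Gln": ("CAA", "CAG"),
    "Asn": ("AAT", "AAC"),
    "Lys": ("AAA", "AAG"),
    "Asp": ("GAT", "GAC"),
    "Glu": ("GAA", "GAG"),
    "Ile": ("ATT", "ATC", "ATA"),
    "Val": ("GTT", "GTC", "GTA", "GTG"),
    "Pro": ("CCT", "CCC", "CCA", "CCG"),
    "Thr": ("ACT", "ACC", "ACA", "ACG"),
    "Ala": ("GCT", "GCC", "GCA", "GCG"),
    "Gly": ("GGT", "GGC", "GGA", "GGG"),
    "Leu": ("TTA", "TTG", "CTT", "CTC", "CTA", "CTG"),
    "Ser": ("TCT", "TCC", "TCA", "TCG", "AGT", "AGC"),
    "Arg": ("CGT", "CGC", "CGA", "CGG", "AGA", "AGG"),
}

_CODON_TO_FAMILY = {
    codon: aa for aa, codons in SYNONYMOUS_FAMILIES.items() for codon in codons
}

# Number of amino-acid families per degeneracy class, and the assembly weights
# of Wright's formula: ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6.
_CLASS_SIZES = {2: 9, 3: 1, 4: 5, 6: 3}

ENC_MIN = 20.0
ENC_MAX = 61.0


class UndefinedResultError(ValueError):
    """Raised when too few codons are observed to assemble ENC."""


class DegenerateBackgroundError(ValueError):
    """Raised when the background assigns zero probability to an observed codon."""


@dataclass(frozen=True)
class Orf:
    """An open reading frame located on a source sequence.

    Coordinates are 0-based half-open on the *forward* strand regardless of
    the strand the ORF was read from; ``sequence`` is the in-frame reading
    (reverse-complemented for minus-strand ORFs).
    """

    id: str
    sequence: str
    strand: str
    frame: int
    start: int
    end: int

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class CodonCounts:
    """Synonymous codon counts aggregated per amino-acid family."""

    counts: dict[str, dict[str, int]] = field(
        default_factory=lambda: {
            aa: {c: 0 for c in codons} for aa, codons in SYNONYMOUS_FAMILIES.items()
        }
    )

    def family_total(self, aa: str) -> int:
        return sum(self.counts[aa].values())

    def total(self) -> int:
        return sum(self.family_total(aa) for aa in self.counts)

    def add(self, other: "CodonCounts") -> "CodonCounts":
        merged = CodonCounts()
        for aa in merged.counts:
            for c in merged.counts[aa]:
                merged.counts[aa][c] = self.counts[aa][c] + other.counts[aa][c]
        return merged


@dataclass(frozen=True)
class Background:
    """Single-nucleotide background frequencies over a coding gene set."""

    freqs: Mapping[str, float]

    def __post_init__(self) -> None:
        total = sum(self.freqs.get(b, 0.0) for b in "ACGT")
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"background frequencies must sum to 1, got {total}")
        if any(self.freqs.get(b, 0.0) < 0 for b in "ACGT"):
            raise ValueError("background frequencies must be nonnegative")

    def codon_weight(self, codon: str) -> float:
        w = 1.0
        for base in codon:
            w *= self.freqs.get(base, 0.0)
        return w

    @classmethod
    def uniform(cls) -> "Background":
        return cls({b: 0.25 for b in "ACGT"})


@dataclass(frozen=True)
class CodonBiasResult:
    enc_all: float
    enc_rib: float
    enc_prime_all: float
    enc_prime_rib: float
    delta_enc_prime: float


_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_orfs(sequence: str, min_len: int = 450, id_prefix: str = "orf") -> list[Orf]:
    """Find all stop-to-stop open stretches of at least ``min_len`` nt.

    Scans all three frames on both strands under the standard genetic code.
    An ORF is a maximal run of non-stop codons; the bounding stop codons are
    not included.  Non-ACGT characters break a run (masked positions cannot
    be called as codons).  An empty sequence yields an empty list.
    """
    if min_len < 3:
        raise ValueError("min_len must be at least 3")
    seq = sequence.upper()
    n = len(seq)
    orfs: list[Orf] = []
    counter = 0
    for strand, s in (("+", seq), ("-", _revcomp(seq))):
        for frame in range(3):
            run_start = frame
            pos = frame
            while pos + 3 <= len(s):
                codon = s[pos : pos + 3]
                if codon in STOP_CODONS or any(b not in "ACGT" for b in codon):
                    if pos - run_start >= min_len:
                        orfs.append(
                            _make_orf(s, run_start, pos, strand, frame, n, id_prefix, counter)
                        )
                        counter += 1
                    run_start = pos + 3
                pos += 3
            if pos - run_start >= min_len:
                orfs.append(_make_orf(s, run_start, pos, strand, frame, n, id_prefix, counter))
                counter += 1
    return orfs


def _make_orf(
    s: str, start: int, end: int, strand: str, frame: int, total_len: int,
    prefix: str, idx: int,
) -> Orf:
    subseq = s[start:end]
    if strand == "+":
        fwd_start, fwd_end = start, end
    else:
        fwd_start, fwd_end = total_len - end, total_len - start
    return Orf(
        id=f"{prefix}_{idx:05d}",
        sequence=subseq,
        strand=strand,
        frame=frame,
        start=fwd_start,
        end=fwd_end,
    )


def count_codons(orfs: Iterable[Orf | str]) -> CodonCounts:
    """Aggregate synonymous codon counts over in-frame sequences.

    Stops, ATG and TGG are excluded from families.  Trailing partial codons
    are dropped with a warning.
    """
    counts = CodonCounts()
    for orf in orfs:
        seq = orf.sequence if isinstance(orf, Orf) else orf
        seq = seq.upper()
        if len(seq) % 3:
            warnings.warn(
                f"sequence length {len(seq)} not divisible by 3; trailing partial codon dropped",
                stacklevel=2,
            )
        for i in range(0, len(seq) - len(seq) % 3, 3):
            codon = seq[i : i + 3]
            aa = _CODON_TO_FAMILY.get(codon)
            if aa is not None:
                counts.counts[aa][codon] += 1
    return counts


def background_from_sequences(sequences: Iterable[str]) -> Background:
    """Mean coding nucleotide frequency over a pooled gene set."""
    tally = {b: 0 for b in "ACGT"}
    for seq in sequences:
        for b in seq.upper():
            if b in tally:
                tally[b] += 1
    total = sum(tally.values())
    if total == 0:
        raise ValueError("no A/C/G/T nucleotides in gene set")
    return Background({b: tally[b] / total for b in "ACGT"})


def _family_f_hat(codon_counts: Mapping[str, int]) -> float | None:
    """Wright's codon homozygosity F̂ = (n·Σp̂² − 1)/(n − 1); None if n < 2."""
    n = sum(codon_counts.values())
    if n < 2:
        return None
    p = np.array(list(codon_counts.values()), dtype=float) / n
    return (n * float(np.sum(p**2)) - 1.0) / (n - 1.0)


def _family_f_hat_prime(codon_counts: Mapping[str, int], background: Background) -> float | None:
    """Composition-corrected homozygosity F̂′ = (χ²ₐ + n − m)/(m·(n − 1))."""
    n = sum(codon_counts.values())
    if n < 2:
        return None
    m = len(codon_counts)
    weights = np.array([background.codon_weight(c) for c in codon_counts], dtype=float)
    obs = np.array(list(codon_counts.values()), dtype=float)
    if weights.sum() <= 0 or np.any((weights == 0) & (obs > 0)):
        raise DegenerateBackgroundError(
            "background assigns zero probability to an observed codon"
        )
    keep = weights > 0
    e = weights[keep] / weights.sum()
    p = obs[keep] / n
    chi2 = n * float(np.sum((p - e) ** 2 / e))
    return (chi2 + n - m) / (m * (n - 1.0))


def _assemble_enc(f_by_family: Mapping[str, float | None]) -> float:
    """Combine per-family homozygosities into the ENC statistic.

    Class means are unweighted over amino acids; families with n<2 or a
    nonpositive homozygosity (possible at small n) are excluded.  A missing
    threefold mean (Ile unobserved) is imputed as (F̄₂+F̄₄)/2; any other
    missing class makes ENC undefined.
    """
    class_vals: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, f in f_by_family.items():
        if f is not None and f > 0:
            class_vals[len(SYNONYMOUS_FAMILIES[aa])].append(f)
    means: dict[int, float] = {}
    for m, vals in class_vals.items():
        if vals:
            means[m] = float(np.mean(vals))
    for m in (2, 4, 6):
        if m not in means:
            raise UndefinedResultError(
                f"no computable family in the {m}-fold degeneracy class"
            )
    if 3 not in means:
        means[3] = (means[2] + means[4]) / 2.0
    value = 2.0 + 9.0 / means[2] + 1.0 / means[3] + 5.0 / means[4] + 3.0 / means[6]
    return min(value, ENC_MAX)


def enc(counts: CodonCounts) -> float:
    """Wright's effective number of codons, capped at 61."""
    return _assemble_enc({aa: _family_f_hat(fc) for aa, fc in counts.counts.items()})


def enc_prime(counts: CodonCounts, background: Background) -> float:
    """Background-corrected effective number of codons (ENC′), capped at 61.

    Under a uniform background the chi-square correction reduces exactly to
    Wright's F̂, so ENC′ equals ENC.
    """
    return _assemble_enc(
        {aa: _family_f_hat_prime(fc, background) for aa, fc in counts.counts.items()}
    )


def delta_enc_prime(
    orfs: Sequence[Orf | tuple[str, str]],
    ribosomal_ids: Iterable[str],
    background: Background | None = None,
) -> CodonBiasResult:
    """ΔENC′ = (ENC′_all − ENC′_rib) / ENC′_all over a coding gene set.

    ``orfs`` may be Orf objects or (id, sequence) pairs.  Codon counts are
    pooled across genes within each set; both sets are corrected against the
    same background (the pooled mean coding nucleotide frequency unless an
    explicit background is supplied).  Positive values mean the ribosomal
    subset is more biased than the coding average, the signature of
    translational selection in fast growers.
    """
    pairs = [
        (o.id, o.sequence) if isinstance(o, Orf) else (o[0], o[1]) for o in orfs
    ]
    rib = set(ribosomal_ids)
    if not rib:
        raise ValueError("ribosomal id set is empty")
    missing = rib - {gid for gid, _ in pairs}
    if missing:
        raise ValueError(f"ribosomal ids not found in gene set: {sorted(missing)[:5]}")
    all_seqs = [seq for _, seq in pairs]
    rib_seqs = [seq for gid, seq in pairs if gid in rib]
    if background is None:
        background = background_from_sequences(all_seqs)
    counts_all = count_codons(all_seqs)
    counts_rib = count_codons(rib_seqs)
    enc_prime_all = enc_prime(counts_all, background)
    enc_prime_rib = enc_prime(counts_rib, background)
    return CodonBiasResult(
        enc_all=enc(counts_all),
        enc_rib=enc(counts_rib),
        enc_prime_all=enc_prime_all,
        enc_prime_rib=enc_prime_rib,
        delta_enc_prime=(enc_prime_all - enc_prime_rib) / enc_prime_all,
    )
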