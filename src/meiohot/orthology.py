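"""Clade-weighted protein conservation profiling and orthologue calling.

The procedure takes a set of protein sequences aligned against a single
reference, plus a taxonomy, and

1. weights each sequence so every major clade contributes equally
   (over-represented clades are down-weighted),
2. computes per-reference-position weighted frequencies over the 20 amino
   acids plus gap (a small pseudocount excludes zero weights),
3. derives per-position entropy (bits) and a normalised Jensen-Shannon
   conservation score,
4. extracts the perfectly conserved and low-entropy (< 1 bit) position sets
   over the consistently aligned region, and
5. accepts or rejects candidate orthologues by how many of the perfectly
   conserved residues they match.

Co-occurrence of two genes across taxa is summarised by a 2x2 table with
sample and conditional-MLE odds ratios and a Fisher exact p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _cmle_odds_ratio

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
NOT_ALIGNED = "."
ALPHABET = AMINO_ACIDS + GAP  # 21 symbols; gap is the 21st

#: rank labels from most to least specific, as used for closest-relative calls
RANK_ORDER = ("species", "genus", "family", "order", "clade", "phylum")

__all__ = [
    "TaxonRecord", "AlignedSequence", "AlignmentSet", "CladeWeights",
    "ConservationProfile", "OrthologueCall", "CoOccurrenceTable",
    "initial_screen", "compute_clade_weights", "position_frequencies",
    "position_entropy", "conserved_sets", "call_orthologue",
    "jsd_conservation", "closest_partner_rank", "cooccurrence_odds_ratio",
    "build_cooccurrence_table", "align_to_reference",
]


@dataclass(frozen=True)
class TaxonRecord:
    """Taxonomic placement of one species.

    ``ranks`` maps rank name -> label for genus, family, order, clade and
    phylum; ``clade_label`` is the label used for equal-clade weighting.
    """

    species_id: str
    ranks: dict[str, str]
    clade_label: str

    def __post_init__(self):
        if not self.clade_label:
            raise ValueError("clade_label must be non-empty")


@dataclass
class AlignedSequence:
    """One sequence expressed in reference coordinates.

    ``residues`` is a string with one character per reference position:
    an amino acid where the sequence aligns, ``-`` for a gap inside the
    aligned span, and ``.`` outside the span (unsequenced / unaligned).
    ``seq_length`` is the full length of the unaligned protein, used for
    reciprocal-coverage screening; it defaults to the number of aligned
    residues.
    """

    species_id: str
    residues: str
    seq_length: int | None = None

    def __post_init__(self):
        bad = set(self.residues) - set(ALPHABET + NOT_ALIGNED)
        if bad:
            raise ValueError(f"invalid residue symbols: {sorted(bad)}")
        if self.seq_length is None:
            self.seq_length = self.n_residues

    @property
    def n_residues(self) -> int:
        return sum(c not in (GAP, NOT_ALIGNED) for c in self.residues)

    @property
    def aligned_span(self) -> tuple[int, int] | None:
        """First and last reference positions covered (half-open end)."""
        idx = [i for i, c in enumerate(self.residues) if c != NOT_ALIGNED]
        if not idx:
            return None
        return idx[0], idx[-1] + 1

    def aligns_at(self, pos: int) -> bool:
        return 0 <= pos < len(self.residues) and self.residues[pos] != NOT_ALIGNED

    @property
    def ungapped(self) -> str:
        return "".join(c for c in self.residues if c not in (GAP, NOT_ALIGNED))


@dataclass
class AlignmentSet:
    """Reference sequence plus species sequences aligned against it."""

    reference: str
    sequences: dict[str, AlignedSequence]
    taxa: dict[str, TaxonRecord] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.reference) == 0:
            raise ValueError("zero-length reference")
        for sid, seq in self.sequences.items():
            if len(seq.residues) != len(self.reference):
                raise ValueError(
                    f"{sid}: aligned length {len(seq.residues)} != reference "
                    f"length {len(self.reference)}"
                )

    def __len__(self) -> int:
        return len(self.sequences)


@dataclass
class CladeWeights:
    """Per-sequence weights; each clade's weights sum to 1."""

    weights: dict[str, float]
    clade_of: dict[str, str]

    def per_clade_sums(self) -> dict[str, float]:
        sums: dict[str, float] = {}
        for sid, w in self.weights.items():
            sums[self.clade_of[sid]] = sums.get(self.clade_of[sid], 0.0) + w
        return sums


def compute_clade_weights(taxa: list[TaxonRecord]) -> CladeWeights:
    """Equal-clade weighting: within a clade of n sequences each gets 1/n.

    The total weight then equals the number of clades, so no single
    over-represented clade (e.g. placental mammals) dominates the
    position frequencies.
    """
    if not taxa:
        raise ValueError("no taxa supplied")
    counts: dict[str, int] = {}
    for t in taxa:
        counts[t.clade_label] = counts.get(t.clade_label, 0) + 1
    weights = {t.species_id: 1.0 / counts[t.clade_label] for t in taxa}
    return CladeWeights(weights, {t.species_id: t.clade_label for t in taxa})


@dataclass
class ConservationProfile:
    """Per-position weighted symbol frequencies and derived scores.

    ``frequencies`` is (n_positions, 21) over :data:`ALPHABET`; each row sums
    to 1 and houses the pseudocount.  ``raw_weight`` is the pseudocount-free
    weighted tally used for the perfect-conservation calls; ``n_contributing``
    counts sequences aligning at each position.
    """

    positions: np.ndarray          # reference positions (0-based)
    frequencies: np.ndarray        # (n_pos, 21), pseudocounted, rows sum to 1
    raw_weight: np.ndarray         # (n_pos, 21), no pseudocount
    n_contributing: np.ndarray     # (n_pos,)
    epsilon: float

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.frequencies, columns=list(ALPHABET))
        df.insert(0, "position", self.positions)
        df["n_contributing"] = self.n_contributing
        df["entropy_bits"] = position_entropy(self)
        return df


def position_frequencies(aln: AlignmentSet, w: CladeWeights,
                         epsilon: float = 1e-5,
                         region: tuple[int, int] | None = None,
                         ) -> ConservationProfile:
    """Weighted 21-symbol frequency vector per reference position.

    Only sequences aligning at a position contribute to it; a gap inside the
    aligned span counts as the 21st symbol.  The pseudocount ``epsilon`` is
    added once per symbol after weighting and the vector renormalised:
    freq(s) = (W_s + eps) / (W + 21 eps).
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    ref_len = len(aln.reference)
    if region is None:
        region = (0, ref_len)
    start, end = region
    if not (0 <= start < end <= ref_len):
        raise ValueError(f"region {region} outside reference [0, {ref_len})")
    positions = np.arange(start, end)
    sym_index = {s: i for i, s in enumerate(ALPHABET)}
    raw = np.zeros((len(positions), 21))
    n_contrib = np.zeros(len(positions), dtype=int)
    for sid, seq in aln.sequences.items():
        weight = w.weights[sid]
        for j, pos in enumerate(positions):
            c = seq.residues[pos]
            if c == NOT_ALIGNED:
                continue
            raw[j, sym_index[c]] += weight
            n_contrib[j] += 1
    freq = raw + epsilon
    freq /= freq.sum(axis=1, keepdims=True)
    return ConservationProfile(positions, freq, raw, n_contrib, epsilon)


def position_entropy(profile: ConservationProfile) -> np.ndarray:
    """Shannon entropy H = -sum p log2 p per position, in bits.

    1 bit corresponds to two residues at equal probability, so the
    low-conservation threshold H < 1 means one residue present in more
    than half the (weighted) species.
    """
    p = profile.frequencies
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p), 0.0)
    return -terms.sum(axis=1)


def conserved_sets(profile: ConservationProfile,
                   entropy_threshold: float = 1.0,
                   ) -> tuple[dict[int, str], np.ndarray]:
    """Perfectly conserved and low-entropy position sets.

    Returns ``(perfect, lowentropy)`` where ``perfect`` maps reference
    position -> the single residue every contributing sequence shows
    (pseudocount ignored; gap-only or mixed columns are excluded), and
    ``lowentropy`` is the array of positions with entropy below the
    threshold.
    """
    if len(profile.positions) == 0:
        raise ValueError("empty region")
    perfect: dict[int, str] = {}
    for j, pos in enumerate(profile.positions):
        nz = np.flatnonzero(profile.raw_weight[j])
        if profile.n_contributing[j] > 0 and len(nz) == 1 and nz[0] < 20:
            perfect[int(pos)] = ALPHABET[nz[0]]
    H = position_entropy(profile)
    lowentropy = profile.positions[H < entropy_threshold]
    return perfect, lowentropy


@dataclass
class OrthologueCall:
    """Verdict for one candidate sequence against the conserved-residue set.

    Two denominators are reported: ``n_conserved_aligned`` counts conserved
    positions inside the candidate's aligned span (a gap there counts as
    aligned but mismatching) while ``n_conserved_nongap`` additionally
    requires a residue. The verdict uses the aligned-span denominator.
    """

    species_id: str
    n_conserved_aligned: int
    n_conserved_nongap: int
    n_conserved_matched: int
    match_fraction: float
    aligned_fraction: float
    accepted: bool
    reason: str
    closest_partner_rank: str | None = None

    def to_dict(self) -> dict:
        return {
            "species_id": self.species_id,
            "n_conserved_aligned": self.n_conserved_aligned,
            "n_conserved_nongap": self.n_conserved_nongap,
            "n_conserved_matched": self.n_conserved_matched,
            "match_fraction": self.match_fraction,
            "aligned_fraction": self.aligned_fraction,
            "accepted": self.accepted,
            "reason": self.reason,
        }


def call_orthologue(seq: AlignedSequence, perfect_set: dict[int, str],
                    match_threshold: float = 0.90,
                    align_threshold: float = 0.50) -> OrthologueCall:
    """Accept a candidate iff it matches >= 90% of the aligned perfectly
    conserved residues and aligns to >= 50% of them.

    The 50% alignment condition admits incomplete sequencing or partial
    protein assemblies without letting short spurious matches through.
    Both thresholds are inclusive.
    """
    if not perfect_set:
        raise ValueError("perfect_set is empty")
    aligned = [p for p in perfect_set if seq.aligns_at(p)]
    nongap = [p for p in aligned if seq.residues[p] != GAP]
    matched = [p for p in nongap if seq.residues[p] == perfect_set[p]]
    if not aligned:
        return OrthologueCall(seq.species_id, 0, 0, 0, 0.0, 0.0,
                              accepted=False, reason="no alignment")
    match_fraction = len(matched) / len(aligned)
    aligned_fraction = len(aligned) / len(perfect_set)
    if aligned_fraction < align_threshold:
        accepted, reason = False, "coverage"
    elif match_fraction < match_threshold:
        accepted, reason = False, "mismatch"
    else:
        accepted, reason = True, "accepted"
    return OrthologueCall(seq.species_id, len(aligned), len(nongap),
                          len(matched), match_fraction, aligned_fraction,
                          accepted, reason)


def initial_screen(seq: AlignedSequence, reference: str,
                   motifs: tuple[str, ...] = ("KWR", "PWWP"),
                   coverage_threshold: float = 0.39) -> tuple[bool, dict]:
    """Screen for 'clear' orthologues: perfect domain-motif matches plus
    reciprocal alignment coverage.

    The candidate must contain every motif (perfect substring match in its
    own residues) and at least ``coverage_threshold`` of the candidate must
    align to the reference and conversely.  The reciprocal condition rejects
    paralogues sharing only a short homologous region (e.g. a ~19% overlap
    needs >2x that coverage to pass at 39%).
    """
    if not reference:
        raise ValueError("missing reference")
    ungapped = seq.ungapped
    has_motifs = all(m in ungapped for m in motifs)
    n_aligned = seq.n_residues
    cov_ref = n_aligned / len(reference)
    cov_seq = n_aligned / seq.seq_length if seq.seq_length else 0.0
    ok = has_motifs and cov_ref >= coverage_threshold and cov_seq >= coverage_threshold
    diagnostics = {
        "has_motifs": has_motifs,
        "coverage_of_reference": cov_ref,
        "coverage_of_sequence": cov_seq,
    }
    return ok, diagnostics


def jsd_conservation(profile: ConservationProfile,
                     background: np.ndarray | None = None) -> np.ndarray:
    """Per-position conservation as z-normalised Jensen-Shannon divergence.

    Each position's gap-excluded, renormalised amino-acid vector is compared
    against a background distribution over the 20 amino acids (uniform by
    default); the raw divergences (base 2) are then standardised to mean 0,
    sd 1 across positions.  Positions where no sequence contributes an
    amino acid score NaN.
    """
    if background is None:
        background = np.full(20, 1 / 20)
    background = np.asarray(background, dtype=float)
    if background.shape != (20,) or background.sum() <= 0 or (background < 0).any():
        raise ValueError("background must be a distribution over 20 amino acids")
    background = background / background.sum()
    aa = profile.frequencies[:, :20]
    totals = aa.sum(axis=1)
    raw = np.full(len(totals), np.nan)
    for j in range(len(totals)):
        if totals[j] <= 0:
            continue
        p = aa[j] / totals[j]
        m = 0.5 * (p + background)
        raw[j] = 0.5 * (stats.entropy(p, m, base=2) + stats.entropy(background, m, base=2))
    valid = ~np.isnan(raw)
    mu, sd = raw[valid].mean(), raw[valid].std()
    if sd == 0:
        return np.where(valid, 0.0, np.nan)
    return (raw - mu) / sd


def closest_partner_rank(species: TaxonRecord,
                         partner_presence: set[str],
                         taxonomy: dict[str, TaxonRecord]) -> str:
    """Most specific taxonomic rank shared with any partner-possessing species.

    Returns "species" if the species itself possesses the partner gene, then
    the first of genus, family, order, clade, phylum shared with a possessing
    species, else "none".
    """
    if species.species_id not in taxonomy:
        raise KeyError(f"{species.species_id} absent from taxonomy")
    if species.species_id in partner_presence:
        return "species"
    partners = [taxonomy[s] for s in partner_presence if s in taxonomy]
    for rank in RANK_ORDER[1:]:
        label = species.ranks.get(rank)
        if label is None:
            continue
        if any(p.ranks.get(rank) == label for p in partners):
            return rank
    return "none"


@dataclass
class CoOccurrenceTable:
    """2x2 co-occurrence summary with both odds-ratio estimators.

    ``sample_or`` is (a d)/(b c); with a zero cell the Haldane-Anscombe 0.5
    correction is applied and flagged.  ``cmle_or`` is the conditional
    maximum-likelihood estimate underlying Fisher's exact test.
    """

    table: np.ndarray
    sample_or: float
    sample_or_corrected: bool
    cmle_or: float
    fisher_p: float

    def summary(self) -> str:
        a, b, c, d = self.table.ravel()
        lines = [
            "2x2 co-occurrence table",
            f"  [[{a}, {b}], [{c}, {d}]]",
            f"  sample odds ratio: {self.sample_or:.4g}"
            + (" (Haldane-Anscombe corrected)" if self.sample_or_corrected else ""),
            f"  conditional-MLE odds ratio: {self.cmle_or:.4g}",
            f"  Fisher exact p (two-sided): {self.fisher_p:.3g}",
        ]
        return "\n".join(lines)


def cooccurrence_odds_ratio(table) -> CoOccurrenceTable:
    """Sample OR, conditional-MLE OR and two-sided Fisher exact p for a 2x2
    table of gene presence/absence counts."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("counts must be non-negative integers")
    if t.sum() == 0:
        raise ValueError("all-zero table")
    a, b, c, d = t.ravel().astype(float)
    corrected = 0.0 in (a, b, c, d)
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    sample_or = (a * d) / (b * c)
    cmle = _cmle_odds_ratio(t, kind="conditional").statistic
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return CoOccurrenceTable(t, sample_or, corrected, float(cmle), float(p))


def build_cooccurrence_table(status: pd.DataFrame,
                             exposure: str, outcome: str) -> np.ndarray:
    """Build the 2x2 table from a per-species status frame.

    One plausible construction of the domain-mutation vs partner-loss test:
    ``exposure`` is a boolean column (e.g. SET catalytic residues mutated)
    and ``outcome`` a boolean column (e.g. no ZCWPW1 orthologue found within
    the species' class/phylum).  Cell [0,0] counts exposure & outcome.
    """
    e = status[exposure].astype(bool)
    o = status[outcome].astype(bool)
    return np.array([
        [int((e & o).sum()), int((e & ~o).sum())],
        [int((~e & o).sum()), int((~e & ~o).sum())],
    ])


def profile_and_call(aln: AlignmentSet, epsilon: float = 1e-5,
                     region: tuple[int, int] | None = None,
                     motifs: tuple[str, ...] = ("KWR", "PWWP"),
                     match_threshold: float = 0.90,
                     align_threshold: float = 0.50,
                     entropy_threshold: float = 1.0) -> dict:
    """Full orthologue-calling procedure.

    Screens sequences for 'clear' orthologues (motif + reciprocal-coverage
    screen), builds the clade-weighted conservation profile from the clear
    set, derives the perfectly conserved and low-entropy position sets, then
    calls every input sequence against the perfectly conserved residues.
    Returns a dict with keys ``clear``, ``weights``, ``profile``,
    ``perfect_set``, ``lowentropy_set`` and ``calls`` (a DataFrame).
    """
    clear = {sid: seq for sid, seq in aln.sequences.items()
             if initial_screen(seq, aln.reference, motifs=motifs)[0]}
    if not clear:
        raise ValueError("no sequence passes the initial screen")
    clear_aln = AlignmentSet(aln.reference, clear, aln.taxa)
    weights = compute_clade_weights([aln.taxa[sid] for sid in clear])
    profile = position_frequencies(clear_aln, weights, epsilon, region=region)
    perfect, lowentropy = conserved_sets(profile, entropy_threshold)
    calls = pd.DataFrame([
        call_orthologue(seq, perfect, match_threshold, align_threshold).to_dict()
        for seq in aln.sequences.values()
    ])
    return {"clear": clear, "weights": weights, "profile": profile,
            "perfect_set": perfect, "lowentropy_set": lowentropy,
            "calls": calls}


def align_to_reference(seq: str, reference: str, species_id: str = "",
                       seq_length: int | None = None) -> AlignedSequence:
    """Local alignment of a raw protein sequence against the reference
    (BLOSUM62, gap open 11 / extend 1), expressed in reference coordinates.

    Intended for synthetic fixtures; real pipelines supply precomputed
    alignments from a search tool.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    alignment = aligner.align(reference, seq)[0]
    residues = [NOT_ALIGNED] * len(reference)
    ref_blocks, seq_blocks = alignment.aligned
    span_start = ref_blocks[0][0]
    span_end = ref_blocks[-1][1]
    residues[span_start:span_end] = [GAP] * (span_end - span_start)
    for (rs, re), (qs, qe) in zip(ref_blocks, seq_blocks):
        for k in range(re - rs):
            residues[rs + k] = seq[qs + k]
    return AlignedSequence(species_id or "query", "".join(residues),
                           seq_length=seq_length or len(seq))
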