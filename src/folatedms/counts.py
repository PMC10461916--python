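"""Variant calling and counting for saturation-mutagenesis amplicon reads.

The mutagenized gene is tiled by non-overlapping sublibrary windows sized so
a merged read pair spans every programmed codon change.  Reads are quality
filtered, compared codon-wise against the wild-type reference, and tallied
into a mutant x timepoint x replicate count table.  A correction subtracts
the expected number of wild-type reads that "hop" onto mutant identities
through sequencing error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

__all__ = [
    "ReferenceMap",
    "CountTable",
    "merge_read_pair",
    "quality_filter",
    "call_variant",
    "tally_counts",
    "correct_wt_hopping",
]

_BASES = "ACGT"
_CODON_TO_AA = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    _CODON_TO_AA[_stop] = "*"
#: amino acid (incl. stop '*') -> list of codons
AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in _CODON_TO_AA.items():
    AA_TO_CODONS.setdefault(_aa, []).append(_codon)

DEFAULT_WINDOWS: tuple[tuple[int, int], ...] = ((1, 40), (41, 80), (81, 120), (121, 159))


def translate_codon(codon: str) -> str:
    return _CODON_TO_AA[codon.upper()]


@dataclass(frozen=True)
class ReferenceMap:
    """Wild-type coding sequence plus the sublibrary window layout.

    Windows are 1-based inclusive codon ranges that tile the gene without
    overlap (default four windows of 40/40/40/39 codons over 159 codons).
    """

    wt_seq: str
    windows: tuple[tuple[int, int], ...] = DEFAULT_WINDOWS

    def __post_init__(self) -> None:
        seq = self.wt_seq.upper()
        object.__setattr__(self, "wt_seq", seq)
        if len(seq) % 3 != 0:
            raise ValueError("wt_seq length must be a multiple of 3")
        if set(seq) - set(_BASES):
            raise ValueError("wt_seq contains non-ACGT characters")
        n = self.n_codons
        covered = []
        for start, end in self.windows:
            if not (1 <= start <= end <= n):
                raise ValueError(f"window ({start},{end}) outside 1..{n}")
            covered.extend(range(start, end + 1))
        if sorted(covered) != list(range(1, n + 1)):
            raise ValueError("windows must tile the gene without overlap")

    @property
    def n_codons(self) -> int:
        return len(self.wt_seq) // 3

    def codon(self, position: int) -> str:
        """WT codon at 1-based codon position."""
        return self.wt_seq[3 * (position - 1) : 3 * position]

    @property
    def wt_protein(self) -> str:
        return str(Seq(self.wt_seq).translate())

    def window_nt_span(self, window: int) -> tuple[int, int]:
        """0-based [start, end) nucleotide span of a window index."""
        start, end = self.windows[window]
        return 3 * (start - 1), 3 * end

    def mutant_id(self, position: int, aa: str) -> str:
        return f"{self.wt_protein[position - 1]}{position}{aa}"


def merge_read_pair(
    fwd: str,
    fwd_qual: Sequence[int],
    rev: str,
    rev_qual: Sequence[int],
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.1,
) -> tuple[str, list[int]] | None:
    """Merge a forward/reverse read pair by best ungapped overlap.

    The reverse read is reverse-complemented, the overlap maximizing
    matched bases is taken, disagreeing positions resolve to the
    higher-quality call (agreeing positions keep the max quality), and the
    pair is rejected (None) when the best overlap is shorter than
    ``min_overlap`` or carries too many mismatches.
    """
    if not fwd or not rev:
        raise ValueError("reads must be non-empty")
    rc = str(Seq(rev).reverse_complement())
    rq = list(rev_qual)[::-1]
    best = None  # (matches, overlap_len, offset)
    max_ov = min(len(fwd), len(rc))
    for ov in range(min_overlap, max_ov + 1):
        a, b = fwd[-ov:], rc[:ov]
        matches = sum(x == y for x, y in zip(a, b))
        if best is None or matches > best[0]:
            best = (matches, ov)
    if best is None:
        return None
    matches, ov = best
    if ov - matches > max_mismatch_frac * ov:
        return None
    merged = list(fwd[:-ov])
    qual = list(fwd_qual[:-ov]) if ov < len(fwd) else []
    fq = list(fwd_qual)
    for i in range(ov):
        fb, rb = fwd[len(fwd) - ov + i], rc[i]
        fqv, rqv = fq[len(fwd) - ov + i], rq[i]
        if fb == rb:
            merged.append(fb)
            qual.append(max(fqv, rqv))
        else:
            merged.append(fb if fqv >= rqv else rb)
            qual.append(max(fqv, rqv))
    merged.extend(rc[ov:])
    qual.extend(rq[ov:])
    return "".join(merged), qual


def quality_filter(
    seq: str, quals: Sequence[int], expected_length: int, q_min: int = 20
) -> bool:
    """Pass iff the read is full expected length and min phred >= q_min."""
    if len(seq) != expected_length or len(quals) != len(seq):
        return False
    return min(quals) >= q_min


def call_variant(
    seq: str, ref: ReferenceMap, window: int, flank_codons: int = 0
):
    """Classify a quality-passed amplicon read against the reference.

    The read is expected to cover the window's codons (plus optional
    flanking codons, truncated at the gene ends).  Returns ``"WT"`` for an
    exact or synonymous match, ``(position, aa)`` for exactly one mutated
    codon inside the window, and ``None`` (reject) for multiple mutations,
    mutations outside the window, or a length mismatch.
    """
    w_start, w_end = ref.windows[window]
    a_start = max(1, w_start - flank_codons)
    a_end = min(ref.n_codons, w_end + flank_codons)
    ref_region = ref.wt_seq[3 * (a_start - 1) : 3 * a_end]
    seq = seq.upper()
    if len(seq) != len(ref_region):
        return None
    mutated = []
    for i in range(len(ref_region) // 3):
        if seq[3 * i : 3 * i + 3] != ref_region[3 * i : 3 * i + 3]:
            mutated.append(a_start + i)
    if not mutated:
        return "WT"
    if len(mutated) > 1:
        return None
    pos = mutated[0]
    if not (w_start <= pos <= w_end):
        return None
    codon = seq[3 * (pos - a_start) : 3 * (pos - a_start) + 3]
    aa = translate_codon(codon)
    if aa == ref.wt_protein[pos - 1]:
        return "WT"  # synonymous codon change counts as WT at the aa level
    return (pos, aa)


@dataclass
class CountTable:
    """Mutant x timepoint x replicate sequencing counts (long format).

    Columns: ``mutant`` (``"WT"`` or an aa-level mutant id), ``position``,
    ``aa``, ``timepoint_h``, ``replicate``, ``count`` (non-negative int).
    A WT row is present for every (timepoint, replicate) sample.
    """

    data: pd.DataFrame

    REQUIRED = ("mutant", "timepoint_h", "replicate", "count")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"CountTable missing columns: {missing}")
        if (self.data["count"] < 0).any():
            raise ValueError("counts must be non-negative")
        for col in ("position", "aa"):
            if col not in self.data.columns:
                self.data[col] = pd.NA
        samples = self.data.groupby(["timepoint_h", "replicate"])
        for key, grp in samples:
            if "WT" not in set(grp["mutant"]):
                raise ValueError(f"WT row missing for sample {key}")
        self.data = self.data.reset_index(drop=True)

    @property
    def timepoints(self) -> list[float]:
        return sorted(self.data["timepoint_h"].unique())

    @property
    def replicates(self) -> list:
        return sorted(self.data["replicate"].unique())

    @property
    def mutants(self) -> list[str]:
        return sorted(set(self.data["mutant"]) - {"WT"})

    def pivot(self, replicate) -> pd.DataFrame:
        """Wide counts for one replicate: mutants x timepoints."""
        sub = self.data[self.data["replicate"] == replicate]
        return sub.pivot_table(
            index="mutant", columns="timepoint_h", values="count", fill_value=0
        )

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CountTable":
        return cls(pd.read_csv(path))


def tally_counts(
    samples: Mapping[tuple, Iterable],
    all_mutants: Sequence[tuple[int, str]] | None = None,
    ref: ReferenceMap | None = None,
) -> CountTable:
    """Tally called reads into a CountTable.

    ``samples`` maps (timepoint_h, replicate) labels to iterables of calls
    (``"WT"`` or ``(position, aa)``); rejected reads (None) are skipped.
    Mutants listed in ``all_mutants`` appear with zero counts even when
    unobserved.  Duplicate sample labels cannot occur in a Mapping by
    construction; callers assembling from files should guard upstream.
    """
    def mid(pos, aa):
        return ref.mutant_id(pos, aa) if ref is not None else f"p{pos}{aa}"

    rows = []
    for (timepoint, replicate), calls in samples.items():
        counts: dict[tuple, int] = {}
        for call in calls:
            if call is None:
                continue
            key = ("WT", None, None) if call == "WT" else (mid(*call), *call)
            counts[key] = counts.get(key, 0) + 1
        counts.setdefault(("WT", None, None), 0)
        if all_mutants is not None:
            for pos, aa in all_mutants:
                counts.setdefault((mid(pos, aa), pos, aa), 0)
        for (mutant, pos, aa), c in counts.items():
            rows.append(
                {
                    "mutant": mutant,
                    "position": pos,
                    "aa": aa,
                    "timepoint_h": timepoint,
                    "replicate": replicate,
                    "count": c,
                }
            )
    return CountTable(pd.DataFrame(rows))


def _hop_probability(wt_codon: str, aa: str, error_rate: float) -> float:
    """P(WT codon read as a codon of ``aa``) under uniform per-base error."""
    p = 0.0
    for codon in AA_TO_CODONS[aa]:
        h = sum(a != b for a, b in zip(codon, wt_codon))
        if h == 0:
            continue
        p += (error_rate / 3.0) ** h * (1.0 - error_rate) ** (3 - h)
    return p


def correct_wt_hopping(
    table: CountTable, ref: ReferenceMap, error_rate: float
) -> CountTable:
    """Subtract expected WT-read hops from each mutant's counts.

    For mutant (position, aa) the expected spurious count in a sample is
    N_WT times the summed probability over codons of that amino acid of
    the WT codon being misread into them (per-base error rate ``e``,
    substitutions uniform over the three alternatives); results are
    floored at zero and the WT count is left unchanged.
    """
    if not (0.0 < error_rate < 1.0):
        raise ValueError("error_rate must be in (0, 1)")
    data = table.data.copy()
    wt = (
        data[data["mutant"] == "WT"]
        .set_index(["timepoint_h", "replicate"])["count"]
        .to_dict()
    )
    hop_cache: dict[tuple[int, str], float] = {}
    new_counts = []
    for row in data.itertuples(index=False):
        if row.mutant == "WT" or pd.isna(row.position):
            new_counts.append(row.count)
            continue
        key = (int(row.position), row.aa)
        if key not in hop_cache:
            hop_cache[key] = _hop_probability(ref.codon(key[0]), key[1], error_rate)
        expected = wt[(row.timepoint_h, row.replicate)] * hop_cache[key]
        new_counts.append(max(row.count - expected, 0.0))
    data["count"] = new_counts
    return CountTable(data)
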