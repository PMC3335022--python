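"""SSU rRNA phylotype clustering at >=99 % pairwise identity.

Sequences sharing at least the identity threshold are grouped into the same
phylotype by deterministic greedy centroid clustering (UCLUST-style):
sequences are processed longest-first and each joins the first existing
centroid it matches at or above the threshold, otherwise it founds a new
phylotype.

Identity is computed from a global alignment with free end gaps (partial
Sanger reads must not be penalized for length): matches / aligned columns,
excluding terminal-gap columns, counting internal gap columns as mismatches.
IUPAC ambiguity codes match when their base sets intersect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "IdentityModel",
    "PhylotypeResult",
    "pairwise_identity",
    "cluster_phylotypes",
    "composition_table",
    "IUPAC_SETS",
]

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "U": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_ALPHABET = "ACGTURYSWKMBDHVN"


@dataclass(frozen=True)
class IdentityModel:
    """Alignment scoring for pairwise identity.

    Global alignment with free end gaps; two symbols score ``match_score``
    when their IUPAC sets intersect, else ``mismatch``.
    """

    match_score: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0


def _build_aligner(model: IdentityModel) -> Align.PairwiseAligner:
    n = len(_ALPHABET)
    data = np.full((n, n), model.mismatch)
    for i, a in enumerate(_ALPHABET):
        for j, b in enumerate(_ALPHABET):
            if IUPAC_SETS[a] & IUPAC_SETS[b]:
                data[i, j] = model.match_score
    matrix = substitution_matrices.Array(alphabet=_ALPHABET, dims=2, data=data)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = model.gap_open
    aligner.extend_gap_score = model.gap_extend
    aligner.end_insertion_score = 0.0  # free end gaps, both sequences
    aligner.end_deletion_score = 0.0
    return aligner


def _validate_seq(seq: str, name: str) -> str:
    if not seq:
        raise ValueError(f"sequence {name} is empty")
    s = seq.upper()
    bad = set(s) - set(_ALPHABET)
    if bad:
        raise ValueError(
            f"sequence {name} contains non-IUPAC symbols: {sorted(bad)}"
        )
    return s


def pairwise_identity(
    seq_a: str, seq_b: str, model: IdentityModel | None = None
) -> float:
    """Percent identity of two sequences under a free-end-gap global alignment.

    Terminal-gap columns (overhangs of the longer sequence) are excluded from
    the denominator; internal gap columns count as mismatches; IUPAC
    ambiguity codes match when their sets intersect.  Symmetric in its
    arguments.
    """
    model = model or IdentityModel()
    a = _validate_seq(seq_a, "a")
    b = _validate_seq(seq_b, "b")
    aligner = _build_aligner(model)
    aln = aligner.align(a, b)[0]
    row_a, row_b = str(aln[0]), str(aln[1])

    def span(row: str) -> tuple[int, int]:
        start = len(row) - len(row.lstrip("-"))
        end = len(row.rstrip("-"))
        return start, end

    a0, a1 = span(row_a)
    b0, b1 = span(row_b)
    start, end = max(a0, b0), min(a1, b1)
    if end <= start:
        return 0.0
    matches = 0
    for ca, cb in zip(row_a[start:end], row_b[start:end]):
        if ca != "-" and cb != "-" and (IUPAC_SETS[ca] & IUPAC_SETS[cb]):
            matches += 1
    return 100.0 * matches / (end - start)


@dataclass
class PhylotypeResult:
    """Sequence->phylotype assignment with centroids and optional composition."""

    assignments: dict[str, str]
    centroids: dict[str, str]  # phylotype id -> centroid sequence id
    threshold: float
    composition: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def n_phylotypes(self) -> int:
        return len(self.centroids)


def cluster_phylotypes(
    seqs: Mapping[str, str],
    threshold: float = 99.0,
    model: IdentityModel | None = None,
) -> PhylotypeResult:
    """Greedy centroid clustering of sequences at a percent-identity threshold.

    Deterministic: sequences are processed longest-first (ties broken by
    lexicographic id); each sequence joins the first existing centroid (in
    founding order) with identity >= threshold, otherwise it founds a new
    phylotype.  Every member therefore satisfies the >=threshold-to-centroid
    invariant by construction; it is re-asserted before returning.
    """
    if len(seqs) == 0:
        raise ValueError("at least one sequence required")
    model = model or IdentityModel()
    order = sorted(seqs, key=lambda sid: (-len(seqs[sid]), sid))
    centroid_ids: list[str] = []
    assignments: dict[str, str] = {}
    identities: dict[str, float] = {}
    for sid in order:
        placed = False
        for k, cid in enumerate(centroid_ids):
            ident = pairwise_identity(seqs[sid], seqs[cid], model)
            if ident >= threshold:
                assignments[sid] = f"PT{k:03d}"
                identities[sid] = ident
                placed = True
                break
        if not placed:
            centroid_ids.append(sid)
            assignments[sid] = f"PT{len(centroid_ids) - 1:03d}"
            identities[sid] = 100.0
    centroids = {f"PT{k:03d}": cid for k, cid in enumerate(centroid_ids)}
    for sid, ident in identities.items():
        assert ident >= threshold, f"member {sid} below threshold to its centroid"
    return PhylotypeResult(
        assignments=assignments, centroids=centroids, threshold=threshold
    )


def composition_table(
    result: PhylotypeResult,
    library_of: Mapping[str, str] | Callable[[str], str],
) -> pd.DataFrame:
    """Counts and within-library relative abundances per phylotype.

    Phylotypes absent from a library are recorded with count 0 (reported as
    'not detected'), never dropped.  Returns a tidy DataFrame with columns
    phylotype, library, count, rel_abundance; also stored on
    ``result.composition``.
    """
    get = library_of.__getitem__ if hasattr(library_of, "__getitem__") else library_of
    rows = []
    for sid, pt in result.assignments.items():
        try:
            lib = get(sid)
        except KeyError:
            raise KeyError(f"unknown sequence id {sid!r} in library map") from None
        rows.append({"seq_id": sid, "phylotype": pt, "library": lib})
    df = pd.DataFrame(rows)
    phylotypes = sorted(result.centroids)
    libraries = sorted(df["library"].unique())
    counts = (
        df.groupby(["phylotype", "library"])
        .size()
        .reindex(
            pd.MultiIndex.from_product(
                [phylotypes, libraries], names=["phylotype", "library"]
            ),
            fill_value=0,
        )
        .reset_index(name="count")
    )
    totals = counts.groupby("library")["count"].transform("sum")
    counts["rel_abundance"] = np.where(
        totals > 0, counts["count"] / totals, 0.0
    )
    result.composition = counts
    return counts
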