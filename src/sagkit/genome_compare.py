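"""Alignment-free and fragment-based genome comparison.

* Tetranucleotide z-score signatures under the maximal-order Markov model
  (expected 4-mer counts from 3-mer and 2-mer counts), pooled over contigs
  and both strands; Pearson correlation of two signatures measures
  compositional relatedness.
* Fragment-based average nucleotide identity (ANI): the query is cut into
  1020 bp fragments, each is located on the reference by exact-match seeds
  and aligned with a bit-parallel gapped aligner; fragments are retained when
  they align at >=30 % identity over >=70 % of their length, and ANI is the
  mean identity of retained fragments.
* Scaffold-level PCA contamination screen: per-scaffold tetramer frequency
  vectors, PCA, and robust (median/MAD) outlier flagging on the first eight
  principal components.
"""

from __future__ import annotations

import re
import warnings
from collections import defaultdict
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .synthdata import GenomeAssembly

__all__ = [
    "TetraSignature",
    "ANIResult",
    "tetra_zscores",
    "tetra_correlation",
    "ani",
    "ani_pair",
    "scaffold_pca_screen",
    "TETRAMERS",
]

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase

TETRAMERS = [
    "".join(t)
    for t in __import__("itertools").product("ACGT", repeat=4)
]


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    rc = np.where(codes < 4, 3 - codes, codes)
    return rc[::-1]


def _kmer_counts(codes: np.ndarray, k: int) -> np.ndarray:
    """Overlapping k-mer counts (step 1); windows with non-ACGT skipped."""
    n = codes.size - k + 1
    if n <= 0:
        return np.zeros(4**k, dtype=np.int64)
    valid = codes < 4
    idx = np.zeros(n, dtype=np.int64)
    ok = np.ones(n, dtype=bool)
    for j in range(k):
        idx = idx * 4 + codes[j : j + n]
        ok &= valid[j : j + n]
    return np.bincount(idx[ok], minlength=4**k).astype(np.int64)


def _pooled_counts(assembly: GenomeAssembly, k: int) -> np.ndarray:
    counts = np.zeros(4**k, dtype=np.int64)
    for _, seq in assembly:
        codes = _encode(seq)
        counts += _kmer_counts(codes, k)
        counts += _kmer_counts(_revcomp_codes(codes), k)
    return counts


@dataclass
class TetraSignature:
    """256 tetranucleotide z-scores in lexicographic ACGT order.

    Entries whose Markov expectation or variance is undefined (absent
    trinucleotide context) are NaN in ``z`` and False in ``defined``; they
    are excluded from correlations, never silently zeroed.
    """

    genome_id: str
    z: np.ndarray
    defined: np.ndarray = field(repr=False)

    @property
    def n_informative(self) -> int:
        return int(self.defined.sum())


def tetra_zscores(assembly: GenomeAssembly, min_length: int = 5000) -> TetraSignature:
    """Tetranucleotide z-scores under the maximal-order Markov model.

    Counts are pooled over all contigs and both strands, so the signature of
    a sequence equals that of its reverse complement exactly.  For tetramer
    n1n2n3n4 the expectation is E = N(n1n2n3) N(n2n3n4) / N(n2n3) and the
    variance is E (N(n2n3) - N(n1n2n3)) (N(n2n3) - N(n2n3n4)) / N(n2n3)^2.
    """
    if not assembly.contigs:
        raise ValueError("empty assembly")
    if assembly.total_length < min_length:
        raise ValueError(
            f"assembly length {assembly.total_length} below the {min_length} bp floor"
        )
    n4 = _pooled_counts(assembly, 4).astype(float)
    n3 = _pooled_counts(assembly, 3).astype(float)
    n2 = _pooled_counts(assembly, 2).astype(float)

    idx = np.arange(256)
    left3 = idx >> 2
    right3 = idx & 63
    mid2 = (idx >> 2) & 15

    with np.errstate(divide="ignore", invalid="ignore"):
        e = n3[left3] * n3[right3] / n2[mid2]
        var = (
            e
            * (n2[mid2] - n3[left3])
            * (n2[mid2] - n3[right3])
            / n2[mid2] ** 2
        )
    defined = (n2[mid2] > 0) & np.isfinite(e) & np.isfinite(var) & (var > 0)
    z = np.full(256, np.nan)
    z[defined] = (n4[defined] - e[defined]) / np.sqrt(var[defined])
    return TetraSignature(genome_id=assembly.genome_id, z=z, defined=defined)


def tetra_correlation(a: TetraSignature, b: TetraSignature) -> float:
    """Pearson correlation of two signatures over jointly defined tetramers."""
    joint = a.defined & b.defined
    if joint.sum() < 10:
        raise ValueError(
            f"only {int(joint.sum())} jointly defined tetramers; need >= 10"
        )
    return float(np.corrcoef(a.z[joint], b.z[joint])[0, 1])


# ---------------------------------------------------------------------------
# average nucleotide identity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ANIResult:
    """One-directional fragment ANI (mean identity of retained fragments)."""

    query_id: str
    ref_id: str
    ani_percent: float | None  # None when no fragment passes the filters
    n_fragments_total: int
    n_fragments_retained: int
    fragment_length: int = 1020
    identity_floor: float = 30.0
    coverage_floor: float = 0.7

    @property
    def defined(self) -> bool:
        return self.ani_percent is not None


_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def _cigar_columns(cigar: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-column (is_match, consumes_query) arrays from an extended CIGAR."""
    match_flags, query_flags = [], []
    for length, op in _CIGAR_RE.findall(cigar):
        n = int(length)
        match_flags.append(np.full(n, op == "=", dtype=bool))
        query_flags.append(np.full(n, op in "=XI", dtype=bool))
    return np.concatenate(match_flags), np.concatenate(query_flags)


def _best_local_segment(
    is_match: np.ndarray, match_score: float = 1.0, penalty: float = -2.0
) -> tuple[int, int]:
    """Maximal-scoring contiguous column range [start, end); (0, 0) if none.

    Trims the banded global alignment to its best local segment, so spurious
    window placements (random sequence) collapse to short segments that fail
    the coverage filter.
    """
    score = np.where(is_match, match_score, penalty)
    prefix = np.concatenate([[0.0], np.cumsum(score)])
    running_min = np.minimum.accumulate(prefix[:-1])
    gains = prefix[1:] - running_min
    end = int(np.argmax(gains))
    if gains[end] <= 0:
        return 0, 0
    start = int(np.argmin(prefix[: end + 1]))
    return start, end + 1


def _index_reference(ref_seq: str, seed_len: int, max_hits: int = 64):
    codes = _encode(ref_seq)
    n = codes.size - seed_len + 1
    index: dict[int, list[int]] = defaultdict(list)
    if n <= 0:
        return index
    valid = codes < 4
    idx = np.zeros(n, dtype=np.int64)
    ok = np.ones(n, dtype=bool)
    for j in range(seed_len):
        idx = idx * 4 + np.where(valid[j : j + n], codes[j : j + n], 0)
        ok &= valid[j : j + n]
    for pos in np.nonzero(ok)[0]:
        bucket = index[int(idx[pos])]
        if len(bucket) < max_hits:
            bucket.append(int(pos))
    return index


def _fragment_seed_kmers(codes: np.ndarray, seed_len: int) -> list[tuple[int, int]]:
    out = []
    for q in range(0, codes.size - seed_len + 1, seed_len):
        window = codes[q : q + seed_len]
        if np.all(window < 4):
            val = 0
            for c in window:
                val = val * 4 + int(c)
            out.append((q, val))
    return out


_RC = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def _align_fragment(
    fragment: str,
    ref_seq: str,
    index,
    seed_len: int,
    band: int,
) -> tuple[float, int] | None:
    """Best (identity_percent, query_span) for one fragment, or None."""
    best = None
    for oriented in (fragment, _revcomp(fragment)):
        codes = _encode(oriented)
        hits: dict[int, int] = defaultdict(int)
        diags: dict[int, list[int]] = defaultdict(list)
        for q, kmer in _fragment_seed_kmers(codes, seed_len):
            for pos in index.get(kmer, ()):
                bucket = (pos - q) // max(band, 1)
                hits[bucket] += 1
                diags[bucket].append(pos - q)
        if not hits:
            continue
        bucket = max(hits, key=lambda b: (hits[b], -b))
        d0 = int(np.median(diags[bucket]))
        lo = max(0, d0 - 2 * band)
        hi = min(len(ref_seq), d0 + len(oriented) + 2 * band)
        window = ref_seq[lo:hi]
        res = edlib.align(oriented, window, mode="HW", task="path")
        if res["editDistance"] < 0 or not res.get("cigar"):
            continue
        is_match, consumes_query = _cigar_columns(res["cigar"])
        start, end = _best_local_segment(is_match)
        if end <= start:
            continue
        ncols = end - start
        identity = 100.0 * float(is_match[start:end].sum()) / ncols
        qspan = int(consumes_query[start:end].sum())
        cand = (identity, qspan)
        if best is None or cand[0] * cand[1] > best[0] * best[1]:
            best = cand
    return best


def _concat(assembly: GenomeAssembly) -> str:
    return ("N" * 64).join(seq for _, seq in assembly)


def ani(
    query: GenomeAssembly,
    ref: GenomeAssembly,
    fragment_length: int = 1020,
    identity_floor: float = 30.0,
    coverage_floor: float = 0.7,
    seed_len: int = 15,
    band: int = 32,
) -> ANIResult:
    """Fragment-based one-directional ANI of ``query`` against ``ref``.

    The query is cut into consecutive ``fragment_length`` bp fragments (the
    final short fragment is dropped).  Each fragment is placed on the
    reference by exact ``seed_len``-mer seeds (both strands), gap-aligned in
    a window around the best seed diagonal, and trimmed to its
    maximal-scoring local segment.  A fragment is retained iff its identity
    is >= ``identity_floor`` percent over a query span of at least
    ``coverage_floor * fragment_length``; ANI is the mean identity of
    retained fragments.  When nothing is retained the result is flagged
    undefined (``ani_percent`` is None), never reported as 0.
    """
    if not query.contigs or not ref.contigs:
        raise ValueError("both assemblies must be non-empty")
    ref_seq = _concat(ref)
    index = _index_reference(ref_seq, seed_len)
    identities = []
    n_total = 0
    for _, contig in query:
        for off in range(0, len(contig) - fragment_length + 1, fragment_length):
            fragment = contig[off : off + fragment_length]
            n_total += 1
            hit = _align_fragment(fragment, ref_seq, index, seed_len, band)
            if hit is None:
                continue
            identity, qspan = hit
            if identity >= identity_floor and qspan >= coverage_floor * fragment_length:
                identities.append(identity)
    return ANIResult(
        query_id=query.genome_id,
        ref_id=ref.genome_id,
        ani_percent=float(np.mean(identities)) if identities else None,
        n_fragments_total=n_total,
        n_fragments_retained=len(identities),
        fragment_length=fragment_length,
        identity_floor=identity_floor,
        coverage_floor=coverage_floor,
    )


def ani_pair(a: GenomeAssembly, b: GenomeAssembly, **kwargs) -> tuple[ANIResult, ANIResult]:
    """Both ANI directions (a->b and b->a); asymmetry is reported, not hidden."""
    return ani(a, b, **kwargs), ani(b, a, **kwargs)


# ---------------------------------------------------------------------------
# scaffold-level PCA contamination screen
# ---------------------------------------------------------------------------


def scaffold_pca_screen(
    assembly: GenomeAssembly,
    n_pcs: int = 8,
    z_cutoff: float = 3.0,
    min_scaffold_length: int = 2000,
) -> pd.DataFrame:
    """Flag compositionally aberrant scaffolds by PCA of tetramer frequencies.

    Each scaffold above the length floor contributes a 256-dim vector of
    relative tetramer frequencies (both strands).  After PCA on the centered
    vectors, a scaffold is flagged when its score on any of the first
    ``n_pcs`` components lies more than ``z_cutoff`` robust standard
    deviations (1.4826 * MAD) from that component's median.  Median/MAD is
    used because contamination itself corrupts mean and SD.

    Returns a DataFrame (scaffold, length, max_abs_robust_z, best_pc,
    flagged) sorted by descending |z|.
    """
    names, lengths, vectors = [], [], []
    for name, seq in assembly:
        if len(seq) < min_scaffold_length:
            continue
        codes = _encode(seq)
        counts = _kmer_counts(codes, 4) + _kmer_counts(_revcomp_codes(codes), 4)
        total = counts.sum()
        if total == 0:
            continue
        names.append(name)
        lengths.append(len(seq))
        vectors.append(counts / total)
    if len(names) < 5:
        raise ValueError(
            f"only {len(names)} usable scaffolds above {min_scaffold_length} bp; need >= 5"
        )
    x = np.asarray(vectors)
    max_pcs = min(n_pcs, len(names) - 1, x.shape[1])
    if max_pcs < n_pcs:
        warnings.warn(
            f"requested {n_pcs} PCs but only {max_pcs} available; truncating",
            stacklevel=2,
        )
    pca = PCA(n_components=max_pcs)
    scores = pca.fit_transform(x - x.mean(axis=0))

    med = np.median(scores, axis=0)
    mad = np.median(np.abs(scores - med), axis=0)
    robust_sd = np.maximum(1.4826 * mad, 1e-15)
    rz = (scores - med) / robust_sd
    max_abs = np.abs(rz).max(axis=1)
    best_pc = np.abs(rz).argmax(axis=1) + 1
    report = pd.DataFrame(
        {
            "scaffold": names,
            "length": lengths,
            "max_abs_robust_z": max_abs,
            "best_pc": best_pc,
            "flagged": max_abs > z_cutoff,
        }
    ).sort_values("max_abs_robust_z", ascending=False, ignore_index=True)
    return report
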