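"""Synthetic data generators for every input the SAG pipeline consumes.

The generators emulate the statistical structure of a fluorescent-substrate
single-cell genomics study of aquatic bacterioplankton:

* flow-cytometry event tables with a rare labeled subpopulation (~0.1 % of
  cell-like events), bead internal standards (~1e5 per mL) and a heat-killed
  control with a >60-fold depleted labeled population;
* sigmoidal MDA (multiple displacement amplification) kinetics whose critical
  point decreases with template amount (0-, 1- and 10-cell wells);
* SSU rRNA amplicon libraries with a known >=99 %-identity phylotype
  structure;
* genomes with taxon-specific tetranucleotide bias (order-3 Markov sources),
  configurable glycoside-hydrolase gene frequency, and partial single-cell
  assemblies with known completeness.

Every generator is deterministic given its seed and emits truth labels next
to the data; downstream modules never read the truth columns (tests do).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CytoSimParams",
    "MdaSimParams",
    "SeqSimParams",
    "GenomeSimParams",
    "KineticsPlate",
    "GenomeAssembly",
    "gen_cytometry_sample",
    "gen_mda_plate",
    "gen_phylotype_library",
    "gen_genome_and_sag",
    "detected_families",
    "DEFAULT_CHANNEL_PARAMS",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# flow cytometry
# ---------------------------------------------------------------------------

#: Per-population (mean, sd) of log10 side scatter and log10 green
#: fluorescence.  Values are chosen so that populations are separable by
#: rectangular gates on a log-log dot plot, as on a real cytometer where
#: 2.15 um calibration beads sit far above bacteria in scatter and the
#: fluorescein signal of labeled cells sits decades above the unlabeled
#: background.
DEFAULT_CHANNEL_PARAMS: dict[str, dict[str, float]] = {
    "unlabeled": {"ssc_mean": 2.0, "ssc_sd": 0.25, "fl1_mean": 0.5, "fl1_sd": 0.25},
    "labeled": {"ssc_mean": 2.0, "ssc_sd": 0.25, "fl1_mean": 3.0, "fl1_sd": 0.20},
    "bead": {"ssc_mean": 3.5, "ssc_sd": 0.08, "fl1_mean": 3.9, "fl1_sd": 0.08},
    "noise": {"ssc_mean": 0.9, "ssc_sd": 0.30, "fl1_mean": 0.4, "fl1_sd": 0.35},
}


@dataclass(frozen=True)
class CytoSimParams:
    """Parameters of a simulated cytometry acquisition.

    ``n_events`` counts cell-like events (labeled + unlabeled) acquired in a
    virtual volume ``acquired_volume_ml`` of the (possibly diluted) sample.
    Bead counts are drawn consistently with ``bead_conc_per_ml`` and that
    volume, which makes the bead-ratio abundance estimator's unbiasedness
    testable: the true labeled-cell concentration in the undiluted sample is
    ``labeled_fraction * n_events * dilution_factor / acquired_volume_ml``.
    """

    n_events: int = 100_000
    labeled_fraction: float = 0.001
    bead_conc_per_ml: float = 1e5
    dilution_factor: float = 1.0
    killed_attenuation: float = 60.0
    channel_params: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_CHANNEL_PARAMS
    )
    noise_fraction: float = 0.05
    acquired_volume_ml: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events <= 0:
            raise ValueError("n_events must be a positive integer")
        if not 0.0 <= self.labeled_fraction <= 1.0:
            raise ValueError("labeled_fraction must lie in [0, 1]")
        if self.killed_attenuation < 1.0:
            raise ValueError("killed_attenuation must be >= 1")
        if self.dilution_factor < 1.0:
            raise ValueError("dilution_factor must be >= 1")
        if self.bead_conc_per_ml <= 0 or self.acquired_volume_ml <= 0:
            raise ValueError("bead_conc_per_ml and acquired_volume_ml must be > 0")
        if not 0.0 <= self.noise_fraction < 1.0:
            raise ValueError("noise_fraction must lie in [0, 1)")
        for pop, chan in self.channel_params.items():
            for key, value in chan.items():
                if not math.isfinite(value):
                    raise ValueError(
                        f"non-finite channel parameter {key!r} for population {pop!r}"
                    )
                if key.endswith("_sd") and value <= 0:
                    raise ValueError(
                        f"channel spread {key!r} for population {pop!r} must be > 0"
                    )

    @property
    def true_labeled_conc_per_ml(self) -> float:
        """Expected labeled-cell concentration in the undiluted sample."""
        return (
            self.labeled_fraction
            * self.n_events
            * self.dilution_factor
            / self.acquired_volume_ml
        )


def gen_cytometry_sample(params: CytoSimParams, killed: bool = False) -> pd.DataFrame:
    """Draw one event table from the four-population mixture.

    Populations: unlabeled cells, substrate-labeled cells, bead internal
    standards and sub-cellular noise.  In the killed control the labeled
    fraction is divided by ``killed_attenuation`` (heat inactivation destroys
    enzymatic substrate binding).

    Returns a DataFrame with columns ``event_id``, ``ssc_log10``,
    ``fl1_log10``, linear ``ssc``/``fl1`` and a ``truth_class`` column; the
    acquisition metadata is stored in ``DataFrame.attrs``.
    """
    rng = np.random.default_rng(params.seed + (1 if killed else 0))
    frac = params.labeled_fraction / (params.killed_attenuation if killed else 1.0)
    n_labeled = int(rng.binomial(params.n_events, frac)) if frac > 0 else 0
    n_unlabeled = params.n_events - n_labeled
    n_beads = int(rng.poisson(params.bead_conc_per_ml * params.acquired_volume_ml))
    n_noise = int(rng.poisson(params.noise_fraction * params.n_events))

    rows = []
    for pop, count in [
        ("unlabeled", n_unlabeled),
        ("labeled", n_labeled),
        ("bead", n_beads),
        ("noise", n_noise),
    ]:
        chan = params.channel_params[pop]
        ssc = rng.normal(chan["ssc_mean"], chan["ssc_sd"], size=count)
        fl1 = rng.normal(chan["fl1_mean"], chan["fl1_sd"], size=count)
        rows.append(
            pd.DataFrame(
                {"ssc_log10": ssc, "fl1_log10": fl1, "truth_class": pop}
            )
        )
    events = pd.concat(rows, ignore_index=True)
    # acquisition order is arbitrary; shuffle so truth classes are interleaved
    events = events.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(
        drop=True
    )
    events.insert(0, "event_id", np.arange(len(events)))
    events["ssc"] = 10.0 ** events["ssc_log10"]
    events["fl1"] = 10.0 ** events["fl1_log10"]
    events.attrs.update(
        {
            "acquired_volume_ml": params.acquired_volume_ml,
            "bead_conc_per_ml": params.bead_conc_per_ml,
            "dilution_factor": params.dilution_factor,
            "killed": killed,
            "true_labeled_conc_per_ml": (
                params.true_labeled_conc_per_ml
                / (params.killed_attenuation if killed else 1.0)
            ),
        }
    )
    return events


# ---------------------------------------------------------------------------
# MDA kinetics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MdaSimParams:
    """Parameters of a simulated 384-well MDA plate.

    The default layout (315 one-cell wells, 66 no-template controls, 3
    ten-cell positive controls) matches the single-cell sorting plate design.
    Each well follows a 4-parameter logistic fluorescence curve whose
    midpoint shifts earlier by ``cp_shift_per_log_template`` hours per decade
    of template (log10(cells + 1)), plus well-to-well jitter and Gaussian
    read noise.
    """

    n_wells_1cell: int = 315
    n_wells_0cell: int = 66
    n_wells_10cell: int = 3
    baseline: float = 100.0
    amplitude: float = 1000.0
    midpoint_hours: float = 10.0
    slope_hours: float = 0.8
    cp_shift_per_log_template: float = 4.0
    well_jitter_sd_hours: float = 0.5
    noise_sd: float = 8.0
    timestep_hours: float = 0.25
    duration_hours: float = 16.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be > 0")
        if self.timestep_hours <= 0:
            raise ValueError("timestep_hours must be > 0")
        if self.duration_hours < self.midpoint_hours:
            raise ValueError("duration must cover the slowest class midpoint")
        if self.n_wells_1cell < 1 or self.n_wells_0cell < 0 or self.n_wells_10cell < 0:
            raise ValueError("well counts invalid")


@dataclass
class KineticsPlate:
    """Long-format MDA kinetics plus per-well truth midpoints.

    ``curves`` columns: well, template_cells, t_hours, fluorescence.
    ``truth`` columns: well, template_cells, true_midpoint_hours.
    """

    curves: pd.DataFrame
    truth: pd.DataFrame

    @property
    def wells(self) -> list[str]:
        return list(self.truth["well"])


def gen_mda_plate(params: MdaSimParams) -> KineticsPlate:
    """Simulate one MDA plate of sigmoidal amplification curves."""
    rng = np.random.default_rng(params.seed)
    t = np.arange(0.0, params.duration_hours + 1e-9, params.timestep_hours)

    wells, templates, midpoints = [], [], []
    layout = [
        (0, params.n_wells_0cell),
        (1, params.n_wells_1cell),
        (10, params.n_wells_10cell),
    ]
    i = 0
    for template, count in layout:
        shift = params.cp_shift_per_log_template * math.log10(template + 1)
        for _ in range(count):
            wells.append(f"W{i:03d}")
            templates.append(template)
            midpoints.append(
                params.midpoint_hours
                - shift
                + rng.normal(0.0, params.well_jitter_sd_hours)
            )
            i += 1

    frames = []
    for well, template, mid in zip(wells, templates, midpoints):
        f = params.baseline + params.amplitude / (
            1.0 + np.exp(-(t - mid) / params.slope_hours)
        )
        if params.noise_sd > 0:
            f = f + rng.normal(0.0, params.noise_sd, size=t.size)
        frames.append(
            pd.DataFrame(
                {
                    "well": well,
                    "template_cells": template,
                    "t_hours": t,
                    "fluorescence": f,
                }
            )
        )
    curves = pd.concat(frames, ignore_index=True)
    truth = pd.DataFrame(
        {
            "well": wells,
            "template_cells": templates,
            "true_midpoint_hours": midpoints,
        }
    )
    return KineticsPlate(curves=curves, truth=truth)


# ---------------------------------------------------------------------------
# SSU rRNA phylotype libraries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SeqSimParams:
    """Parameters of a simulated amplicon library with phylotype structure.

    ``within_divergence`` is the per-site substitution proportion applied to
    each member relative to its phylotype ancestor; ``between_divergence`` is
    the per-site divergence of each ancestor from a common root, so realized
    ancestor-ancestor divergence is close to twice this value and is
    explicitly verified.  Substitutions only (no indels), uppercase ACGT.
    """

    n_phylotypes: int = 5
    seqs_per_phylotype: int = 4
    seq_length: int = 800
    within_divergence: float = 0.005
    between_divergence: float = 0.05
    library_labels: Sequence[str] = ("syto9", "laminarin")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_phylotypes < 1 or self.seqs_per_phylotype < 1:
            raise ValueError("counts must be >= 1")
        if self.seq_length < 10:
            raise ValueError("seq_length too short")
        if not 0.0 <= self.within_divergence < 0.01:
            raise ValueError(
                "within_divergence must lie in [0, 0.01) to respect the 99% "
                "phylotype threshold"
            )
        if self.between_divergence <= self.within_divergence:
            raise ValueError(
                "between_divergence must exceed within_divergence; the "
                "requested parameters cannot guarantee cluster separation"
            )


def _mutate(seq: np.ndarray, divergence: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute exactly round(divergence * len) distinct sites to new bases."""
    n_mut = int(round(divergence * seq.size))
    if n_mut == 0:
        return seq.copy()
    sites = rng.choice(seq.size, size=n_mut, replace=False)
    out = seq.copy()
    # shift by 1..3 in base space guarantees a different base at every site
    out[sites] = (out[sites] + rng.integers(1, 4, size=n_mut)) % 4
    return out


def _codes_to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def gen_phylotype_library(
    params: SeqSimParams,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Generate an amplicon library with known phylotype partition.

    Returns ``(sequences, truth)`` where ``sequences`` maps sequence id to an
    uppercase ACGT string and ``truth`` has columns ``seq_id``, ``phylotype``,
    ``library``.  Realized ancestor-ancestor divergence is verified to be at
    least ``between_divergence``; member sequences carry exactly
    ``round(within_divergence * seq_length)`` substitutions from their
    ancestor.
    """
    rng = np.random.default_rng(params.seed)
    root = rng.integers(0, 4, size=params.seq_length).astype(np.int64)
    ancestors = [
        _mutate(root, params.between_divergence, rng)
        for _ in range(params.n_phylotypes)
    ]
    # verify realized pairwise ancestor divergence
    for i in range(len(ancestors)):
        for j in range(i + 1, len(ancestors)):
            frac = float(np.mean(ancestors[i] != ancestors[j]))
            if frac < params.between_divergence:
                raise ValueError(
                    "realized ancestor divergence "
                    f"{frac:.4f} below requested between_divergence; "
                    "increase seq_length or between_divergence"
                )

    libs = list(params.library_labels)
    # each phylotype prefers one library (cyclic), 75/25 mixture when >1 lib:
    # gives libraries distinct compositions for beta-diversity tests
    seqs: dict[str, str] = {}
    records = []
    for p, anc in enumerate(ancestors):
        for m in range(params.seqs_per_phylotype):
            member = _mutate(anc, params.within_divergence, rng)
            sid = f"P{p:02d}_S{m:02d}"
            seqs[sid] = _codes_to_str(member)
            if len(libs) == 1:
                lib = libs[0]
            else:
                preferred = libs[p % len(libs)]
                others = [x for x in libs if x != preferred]
                lib = (
                    preferred
                    if rng.random() < 0.75
                    else others[int(rng.integers(len(others)))]
                )
            records.append({"seq_id": sid, "phylotype": f"phylo{p:02d}", "library": lib})
    truth = pd.DataFrame(records)
    return seqs, truth


# ---------------------------------------------------------------------------
# genomes and partial single-cell assemblies
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeSimParams:
    """Parameters of one simulated genome and its partial SAG assembly.

    ``taxon_profile`` selects a reproducible order-3 Markov composition bias
    (two genomes with the same profile share a tetranucleotide signature;
    different profiles diverge).  ``completeness`` is the fraction of the
    genome retained in the partial assembly, emulating the 30--90 % genome
    recovery typical of single amplified genomes.
    """

    genome_length_bp: int = 1_000_000
    taxon_profile: str = "verruco"
    gh_frequency: float = 0.012
    genes_per_kb: float = 1.0
    gene_length_bp: int = 900
    completeness: float = 0.6
    n_contigs: int = 10
    n_cscg: int = 273
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.completeness <= 1.0:
            raise ValueError("completeness must lie in (0, 1]")
        if not 0.0 <= self.gh_frequency <= 1.0:
            raise ValueError("gh_frequency must lie in [0, 1]")
        if self.genome_length_bp < 10_000:
            raise ValueError("genome_length_bp too small")
        if self.n_contigs < 1:
            raise ValueError("n_contigs must be >= 1")
        retained = self.completeness * self.genome_length_bp
        if retained < self.n_contigs:
            raise ValueError(
                "n_contigs segments are infeasible for the requested "
                "completeness and genome length"
            )


@dataclass
class GenomeAssembly:
    """A named set of contigs (uppercase ACGT strings)."""

    genome_id: str
    contigs: dict[str, str]

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def __iter__(self):
        return iter(self.contigs.items())


def _profile_transition_matrix(profile: str) -> np.ndarray:
    """Deterministic 64x4 order-3 transition matrix for a taxon profile.

    The profile string seeds a Dirichlet draw, so the bias is stable across
    genome seeds: genomes of one taxon share composition, distinct taxa
    differ.
    """
    h = np.frombuffer(profile.encode("utf-8"), dtype=np.uint8)
    seed = int(np.sum(h.astype(np.uint64) * np.arange(1, h.size + 1, dtype=np.uint64)))
    prng = np.random.default_rng(seed % (2**31))
    return prng.dirichlet(np.full(4, 4.0), size=64)


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    @njit(cache=True)
    def _markov_chain(cum: np.ndarray, u: np.ndarray, start: int) -> np.ndarray:
        n = u.size
        out = np.empty(n, dtype=np.uint8)
        state = start
        for i in range(n):
            row = cum[state]
            x = u[i]
            b = 0
            while b < 3 and x >= row[b]:
                b += 1
            out[i] = b
            state = ((state << 2) & 63) | b
        return out

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def _markov_chain_py(cum: np.ndarray, u: np.ndarray, start: int) -> np.ndarray:
    out = np.empty(u.size, dtype=np.uint8)
    state = start
    for i in range(u.size):
        b = int(np.searchsorted(cum[state], u[i], side="right"))
        out[i] = min(b, 3)
        state = ((state << 2) & 63) | out[i]
    return out


def _gen_markov_sequence(
    length: int, profile: str, rng: np.random.Generator
) -> np.ndarray:
    trans = _profile_transition_matrix(profile)
    cum = np.cumsum(trans, axis=1)
    cum[:, -1] = 1.0 + 1e-12
    u = rng.random(length)
    start = int(rng.integers(64))
    if _HAVE_NUMBA:
        return _markov_chain(cum, u, start)
    return _markov_chain_py(cum, u, start)


_GENE_CLASSES = ["GH", "GT", "sulfatase", "peptidase", "lyase_esterase", "other"]


def _assign_gene_classes(
    n_genes: int, gh_frequency: float, rng: np.random.Generator
) -> list[str]:
    # background frequencies loosely shaped like a hydrolytic marine genome:
    # glycoside transferases, sulfatases, peptidases and lyases/esterases are
    # each rarer than 'other'; GH takes the requested share.
    rest = 1.0 - gh_frequency
    probs = np.array([gh_frequency, 0.01, 0.01, 0.04, 0.005, 0.0])
    probs[5] = rest - probs[1:5].sum()
    if probs[5] < 0:
        probs[1:5] *= rest / probs[1:5].sum()
        probs[5] = 0.0
    draws = rng.choice(len(_GENE_CLASSES), size=n_genes, p=probs / probs.sum())
    return [_GENE_CLASSES[i] for i in draws]


def _sample_segments(
    genome_len: int, total_retained: int, n_contigs: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Choose non-overlapping (start, end) segments with the given total length."""
    # split retained length into n parts, then place them by distributing the
    # leftover gap length around them (stick-breaking)
    parts = rng.dirichlet(np.full(n_contigs, 5.0)) * total_retained
    parts = np.maximum(1, np.round(parts).astype(int))
    # fix rounding drift
    diff = total_retained - int(parts.sum())
    parts[0] = max(1, parts[0] + diff)
    gap_total = genome_len - int(parts.sum())
    if gap_total < 0:
        raise ValueError("retained length exceeds genome length")
    gaps = rng.dirichlet(np.full(n_contigs + 1, 1.0)) * gap_total
    gaps = np.floor(gaps).astype(int)
    segments = []
    pos = 0
    for k in range(n_contigs):
        pos += int(gaps[k])
        segments.append((pos, pos + int(parts[k])))
        pos += int(parts[k])
    return segments


def gen_genome_and_sag(
    params: GenomeSimParams,
) -> tuple[GenomeAssembly, GenomeAssembly, pd.DataFrame]:
    """Simulate a complete genome, a partial SAG assembly and annotations.

    Returns ``(complete, partial, annotations)``.  The complete genome is a
    single replicon drawn from the taxon's order-3 Markov source.  The
    partial assembly consists of ``n_contigs`` non-overlapping genome
    segments whose total length is ``round(completeness * genome_length)``.

    The annotation table has the reader-facing columns ``genome_id``,
    ``gene_id``, ``class``, ``copies`` plus generator-truth columns ``start``,
    ``end`` and ``family`` (the first ``n_cscg`` genes carry conserved
    single-copy family ids ``CSCG0000``...), which let tests and the
    completeness pipeline detect families by coordinate bookkeeping.
    """
    rng = np.random.default_rng(params.seed)
    codes = _gen_markov_sequence(params.genome_length_bp, params.taxon_profile, rng)
    gid = f"{params.taxon_profile}_{params.seed}"
    complete = GenomeAssembly(genome_id=gid, contigs={f"{gid}_genome": _codes_to_str(codes)})

    n_genes = max(
        params.n_cscg, int(round(params.genome_length_bp * params.genes_per_kb / 1000.0))
    )
    max_start = params.genome_length_bp - params.gene_length_bp
    starts = np.sort(rng.choice(max_start, size=n_genes, replace=False))
    classes = _assign_gene_classes(n_genes, params.gh_frequency, rng)
    families = [
        f"CSCG{k:04d}" if k < params.n_cscg else f"FAM{k:05d}"
        for k in rng.permutation(n_genes)
    ]
    annotations = pd.DataFrame(
        {
            "genome_id": gid,
            "gene_id": [f"{gid}_g{k:05d}" for k in range(n_genes)],
            "class": classes,
            "copies": 1,
            "start": starts,
            "end": starts + params.gene_length_bp,
            "family": families,
        }
    )

    total_retained = int(round(params.completeness * params.genome_length_bp))
    if params.completeness == 1.0 and params.n_contigs == 1:
        segments = [(0, params.genome_length_bp)]
    else:
        segments = _sample_segments(
            params.genome_length_bp, total_retained, params.n_contigs, rng
        )
    contigs = {
        f"{gid}_c{k:03d}": _codes_to_str(codes[s:e])
        for k, (s, e) in enumerate(segments)
    }
    partial = GenomeAssembly(genome_id=f"{gid}_sag", contigs=contigs)
    partial_meta = {
        "segments": segments,
        "true_completeness": params.completeness,
        "true_genome_length": params.genome_length_bp,
    }
    # attach truth out-of-band; GenomeAssembly stays a plain contig container
    partial.truth = partial_meta  # type: ignore[attr-defined]
    return complete, partial, annotations


def detected_families(
    partial: GenomeAssembly, annotations: pd.DataFrame, prefix: str = "CSCG"
) -> set[str]:
    """Families whose gene interval is fully covered by a retained segment.

    Mirrors homology-based single-copy gene detection in a SAG assembly by
    coordinate bookkeeping: a family is detected iff its gene lies entirely
    inside one of the partial assembly's genome segments.
    """
    segments = partial.truth["segments"]  # type: ignore[attr-defined]
    found: set[str] = set()
    rows = annotations[annotations["family"].str.startswith(prefix)]
    seg_arr = np.array(segments)
    for start, end, fam in zip(rows["start"], rows["end"], rows["family"]):
        if np.any((seg_arr[:, 0] <= start) & (seg_arr[:, 1] >= end)):
            found.add(fam)
    return found
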