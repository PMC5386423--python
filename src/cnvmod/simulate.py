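"""Synthetic SNP-array cohorts with known truth.

Generates everything the pipeline consumes: a probe grid with exponential
inter-probe spacing, per-sample LRR/BAF intensity signals with embedded
deletion segments (Gaussian noise, sinusoidal waviness, optional BAF drift),
deletion-carrier genotypes over a configurable locus frequency spectrum, and
censored age-at-onset phenotypes sampled under the two-stratum ascertainment
design of a case-enriched BRCA1-carrier cohort (breast cancer diagnosed
before 40 versus unaffected / first ovarian cancer at 35 or later).

Every output is a deterministic function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import AscertainmentError, ValidationError
from .incidence import IncidenceModel, default_breast_incidence, default_ovarian_incidence
from .io import IntensityReport, write_intensity_report, write_phenotypes

__all__ = [
    "SignalModel",
    "CnvLocus",
    "TruthSet",
    "make_probe_grid",
    "place_deletion_loci",
    "simulate_cnv_genotypes",
    "simulate_intensities",
    "simulate_phenotypes",
    "make_truth_set",
]


@dataclass(frozen=True)
class SignalModel:
    """Distributional model of the array signal.

    LRR is the per-copy-number mean plus sinusoidal waviness plus Gaussian
    noise; BAF is drawn from the genotype clusters implied by the copy number
    at a per-probe population B-allele frequency (uniform on [0,1]), with
    Gaussian cluster noise, clipped to [0,1].  ``baf_drift`` pulls the
    homozygote clusters toward the middle (the drifted-homozygote artifact).
    """

    lrr_means: tuple = (-3.5, -0.66, 0.0, 0.40, 0.68)
    lrr_sd: float = 0.15
    baf_sd: float = 0.03
    waviness_amplitude: float = 0.01
    waviness_wavelength_bp: float = 4e6
    baf_drift: float = 0.0

    def __post_init__(self):
        if self.lrr_means[1] >= 0:
            raise ValidationError("copy-1 LRR mean must be negative")
        for v in (self.lrr_sd, self.baf_sd, self.waviness_amplitude):
            if v < 0:
                raise ValidationError("signal scales must be >= 0")


@dataclass(frozen=True)
class CnvLocus:
    name: str
    chromosome: str
    start: int
    end: int
    frequency: float
    copy_number: int = 1  # heterozygous deletion by default

    def __post_init__(self):
        if not 0.0 <= self.frequency <= 1.0:
            raise ValidationError(f"locus {self.name!r}: frequency outside [0,1]")
        if self.start > self.end:
            raise ValidationError(f"locus {self.name!r}: start > end")


def make_probe_grid(n_chromosomes: int, probes_per_chromosome: int,
                    mean_spacing_bp: int, seed: int) -> pd.DataFrame:
    """Probe grid with exponential inter-probe gaps of the given mean.

    Returns a frame with ``probe_id``, ``chromosome`` (chr1..chrN) and
    strictly increasing 1-based ``position`` per chromosome.
    """
    if min(n_chromosomes, probes_per_chromosome, mean_spacing_bp) < 1:
        raise ValidationError("all grid parameters must be >= 1")
    rng = np.random.default_rng(seed)
    frames = []
    for c in range(1, n_chromosomes + 1):
        gaps = np.maximum(1, np.round(rng.exponential(mean_spacing_bp,
                                                      probes_per_chromosome))).astype(np.int64)
        pos = 10_000 + np.cumsum(gaps)
        frames.append(pd.DataFrame({
            "probe_id": [f"p{c}_{i}" for i in range(probes_per_chromosome)],
            "chromosome": f"chr{c}",
            "position": pos,
        }))
    return pd.concat(frames, ignore_index=True)


def place_deletion_loci(grid: pd.DataFrame, frequencies, seed: int,
                        probes_per_locus=(12, 25), min_gap_probes: int = 50) -> list:
    """Place non-overlapping deletion loci on probe windows of the grid."""
    rng = np.random.default_rng(seed)
    loci = []
    chroms = list(pd.unique(grid["chromosome"]))
    taken = {c: [] for c in chroms}
    for k, freq in enumerate(frequencies):
        for _ in range(1000):
            chrom = chroms[int(rng.integers(len(chroms)))]
            pos = grid.loc[grid["chromosome"] == chrom, "position"].to_numpy()
            width = int(rng.integers(probes_per_locus[0], probes_per_locus[1] + 1))
            if pos.size < width + 2 * min_gap_probes:
                continue
            i = int(rng.integers(min_gap_probes, pos.size - width - min_gap_probes))
            j = i + width - 1
            if all(j + min_gap_probes < a or i - min_gap_probes > b for a, b in taken[chrom]):
                taken[chrom].append((i, j))
                loci.append(CnvLocus(name=f"GENE{k + 1}", chromosome=chrom,
                                     start=int(pos[i]), end=int(pos[j]), frequency=float(freq)))
                break
        else:
            raise ValidationError("could not place loci without overlap")
    return loci


def simulate_cnv_genotypes(loci, n_samples: int, seed: int) -> pd.DataFrame:
    """Independent Bernoulli carrier draws per locus per sample.

    Loci on one chromosome must not overlap.  Returns a binary frame indexed
    by generated sample names with one column per locus.
    """
    by_chrom = {}
    for loc in loci:
        by_chrom.setdefault(loc.chromosome, []).append(loc)
    for group in by_chrom.values():
        group = sorted(group, key=lambda l: l.start)
        for a, b in zip(group[:-1], group[1:]):
            if b.start <= a.end:
                raise ValidationError(f"loci {a.name!r} and {b.name!r} overlap")
    rng = np.random.default_rng(seed)
    z = np.column_stack([
        (rng.random(n_samples) < loc.frequency).astype(np.int8) for loc in loci
    ]) if loci else np.zeros((n_samples, 0), dtype=np.int8)
    index = [f"S{i + 1:05d}" for i in range(n_samples)]
    return pd.DataFrame(z, index=index, columns=[loc.name for loc in loci])


def _truth_segments(z: pd.DataFrame, loci) -> pd.DataFrame:
    rows = []
    by_name = {loc.name: loc for loc in loci}
    for sample in z.index:
        for name in z.columns:
            if z.loc[sample, name]:
                loc = by_name[name]
                rows.append((sample, loc.chromosome, loc.start, loc.end,
                             loc.copy_number, name))
    return pd.DataFrame(rows, columns=["sample", "chromosome", "start", "end",
                                       "copy_number", "locus"])


def simulate_intensities(grid: pd.DataFrame, segments: pd.DataFrame, samples,
                         model: SignalModel, seed: int) -> IntensityReport:
    """LRR/BAF signals for the given samples with embedded truth segments."""
    rng = np.random.default_rng(seed)
    n_probes = len(grid)
    n_samples = len(samples)
    pos = grid["position"].to_numpy()
    chrom = grid["chromosome"].to_numpy()
    sample_idx = {s: j for j, s in enumerate(samples)}

    copy = np.full((n_probes, n_samples), 2, dtype=np.int8)
    for _, seg in segments.iterrows():
        j = sample_idx.get(seg["sample"])
        if j is None:
            continue
        m = (chrom == seg["chromosome"]) & (pos >= seg["start"]) & (pos <= seg["end"])
        copy[m, j] = seg["copy_number"]

    means = np.asarray(model.lrr_means)[copy]
    phase = rng.uniform(0, 2 * np.pi, size=n_samples)
    wave = model.waviness_amplitude * np.sin(
        2 * np.pi * pos[:, None] / model.waviness_wavelength_bp + phase[None, :]
    )
    lrr = means + wave + rng.normal(0.0, model.lrr_sd, size=(n_probes, n_samples))

    pop_b = rng.random(n_probes)  # population B-allele frequency per probe
    b_count = rng.binomial(np.maximum(copy, 1), pop_b[:, None])
    with np.errstate(invalid="ignore"):
        baf_mean = np.where(copy > 0, b_count / np.maximum(copy, 1), 0.0)
    if model.baf_drift > 0:
        baf_mean = baf_mean * (1 - 2 * model.baf_drift) + model.baf_drift
    baf = baf_mean + rng.normal(0.0, model.baf_sd, size=(n_probes, n_samples))
    # copy-0 probes have no genotype: BAF is pure noise, uniform on [0,1]
    zero = copy == 0
    if zero.any():
        baf[zero] = rng.random(int(zero.sum()))
    baf = np.clip(baf, 0.0, 1.0)
    return IntensityReport(probes=grid.copy(), samples=list(samples), lrr=lrr, baf=baf)


def simulate_phenotypes(carriers: pd.DataFrame, locus: str, beta: float,
                        incidence_breast: IncidenceModel,
                        incidence_ovarian: IncidenceModel,
                        n_target_per_stratum: int, seed: int,
                        censoring=(35.0, 75.0), endpoint: str = "breast"):
    """Ascertained phenotypes for candidates in ``carriers`` (the pool).

    Ages at onset are drawn by inverting the piecewise-exponential survival
    function under hazard ``lambda0(t) * exp(beta * z)`` for the chosen
    endpoint (the other endpoint keeps its baseline hazard); an independent
    censoring age is uniform on ``censoring``.  Candidates are taken in pool
    order and assigned to stratum A (breast cancer diagnosed before 40) or
    stratum B (no breast cancer, and any ovarian cancer at 35 or later)
    until each stratum holds ``n_target_per_stratum`` samples.

    Returns ``(phenotypes, info)`` where phenotypes has the standard columns
    plus ``stratum``, and info records the acceptance rate.  Raises
    :class:`AscertainmentError` if the pool cannot fill a stratum.
    """
    if not np.isfinite(beta):
        raise ValidationError("beta must be finite")
    rng = np.random.default_rng(seed)
    n_pool = len(carriers)
    z = carriers[locus].to_numpy() if locus in carriers.columns else np.zeros(n_pool)
    r_bc = np.exp(beta * z) if endpoint == "breast" else np.ones(n_pool)
    r_oc = np.exp(beta * z) if endpoint == "ovarian" else np.ones(n_pool)

    t_bc = incidence_breast.inverse_cumulative_hazard(rng.exponential(1.0, n_pool) / r_bc)
    t_oc = incidence_ovarian.inverse_cumulative_hazard(rng.exponential(1.0, n_pool) / r_oc)
    c_age = rng.uniform(censoring[0], censoring[1], n_pool)

    bc_obs = t_bc <= c_age
    oc_obs = t_oc <= c_age
    in_a = bc_obs & (t_bc < 40.0)
    in_b = ~bc_obs & (~oc_obs | (t_oc >= 35.0))

    idx_a = np.flatnonzero(in_a)
    idx_b = np.flatnonzero(in_b)
    if idx_a.size < n_target_per_stratum or idx_b.size < n_target_per_stratum:
        raise AscertainmentError(
            f"pool of {n_pool} yields {idx_a.size} stratum-A and {idx_b.size} "
            f"stratum-B candidates; need {n_target_per_stratum} each"
        )
    idx_a = idx_a[:n_target_per_stratum]
    idx_b = idx_b[:n_target_per_stratum]
    attempts = int(max(idx_a[-1], idx_b[-1])) + 1
    accepted = np.sort(np.concatenate([idx_a, idx_b]))

    stratum = np.where(np.isin(accepted, idx_a), "A", "B")
    phen = pd.DataFrame({
        "sample": carriers.index.to_numpy()[accepted],
        "age_bc_dx": np.where(bc_obs[accepted], t_bc[accepted], np.nan),
        "age_oc_dx": np.where(oc_obs[accepted], t_oc[accepted], np.nan),
        "age_mastectomy": np.nan,
        "age_oophorectomy": np.nan,
        "age_last_obs": c_age[accepted],
        "stratum": stratum,
    })
    info = {
        "attempts": attempts,
        "accepted": int(accepted.size),
        "acceptance_rate": accepted.size / attempts,
    }
    return phen, info


@dataclass
class TruthSet:
    """Ground truth and generated inputs for one synthetic cohort."""

    loci: list
    segments: pd.DataFrame
    z: pd.DataFrame  # accepted samples x loci
    phenotypes: pd.DataFrame
    report: IntensityReport = field(repr=False)
    transcripts: pd.DataFrame
    params: dict

    @property
    def samples(self) -> list:
        return list(self.z.index)

    def to_tsv(self, outdir) -> None:
        """Write all generated tables (plain text) to a directory."""
        import pathlib
        import yaml

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.segments.to_csv(out / "truth_segments.tsv", sep="\t", index=False)
        self.z.rename_axis("sample").to_csv(out / "truth_carriers.tsv", sep="\t")
        write_phenotypes(self.phenotypes, out / "phenotypes.tsv")
        self.transcripts.to_csv(out / "transcripts.tsv", sep="\t", index=False)
        write_intensity_report(self.report, out / "intensities.tsv")
        with open(out / "truth_params.yaml", "w") as fh:
            yaml.safe_dump(self.params, fh, sort_keys=True)


def _default_frequencies(n_loci: int, causal_frequency: float):
    """Null-locus carrier frequencies spanning the reported 0.2-8.2% spectrum."""
    others = np.geomspace(0.005, 0.05, max(n_loci - 1, 1))
    return [causal_frequency] + [float(f) for f in others][: n_loci - 1]


def make_truth_set(
    n_chromosomes: int = 2,
    probes_per_chromosome: int = 2000,
    mean_spacing_bp: int = 5000,
    n_loci: int = 5,
    causal_locus: str = "GENE1",
    causal_frequency: float = 0.10,
    frequencies=None,
    beta: float = float(np.log(2.0)),
    endpoint: str = "breast",
    n_target_per_stratum: int = 100,
    signal: SignalModel | None = None,
    incidence_breast: IncidenceModel | None = None,
    incidence_ovarian: IncidenceModel | None = None,
    pool_factor: int = 60,
    seed: int = 0,
) -> TruthSet:
    """Generate a complete synthetic cohort with known truth.

    The causal locus carries log relative risk ``beta`` on the chosen
    endpoint; all other loci are null.  The causal carrier frequency
    defaults to 10%, near the top of the reported deletion frequency spectrum,
    which gives the scaled-down cohort usable power.  Deterministic under
    ``seed``; sub-streams are spawned for the grid, genotypes, phenotypes
    and intensities.
    """
    signal = signal or SignalModel()
    incidence_breast = incidence_breast or default_breast_incidence()
    incidence_ovarian = incidence_ovarian or default_ovarian_incidence()
    ss = np.random.SeedSequence(seed)
    s_grid, s_loci, s_geno, s_phen, s_inten = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(5)
    )

    grid = make_probe_grid(n_chromosomes, probes_per_chromosome, mean_spacing_bp, s_grid)
    freqs = frequencies or _default_frequencies(n_loci, causal_frequency)
    if len(freqs) != n_loci:
        raise ValidationError("need one frequency per locus")
    loci = place_deletion_loci(grid, freqs, s_loci)

    pool = simulate_cnv_genotypes(loci, pool_factor * n_target_per_stratum, s_geno)
    phen, info = simulate_phenotypes(
        pool, causal_locus, beta, incidence_breast, incidence_ovarian,
        n_target_per_stratum, s_phen, endpoint=endpoint,
    )
    z = pool.loc[phen["sample"]]
    segments = _truth_segments(z, loci)
    report = simulate_intensities(grid, segments, list(z.index), signal, s_inten)

    # two transcripts per locus exercise the transcript-union rule downstream
    rows = []
    for loc in loci:
        rows.append((loc.name, loc.chromosome, loc.start, loc.end))
        third = max(1, (loc.end - loc.start) // 3)
        rows.append((loc.name, loc.chromosome, loc.start + third, loc.end))
    transcripts = pd.DataFrame(rows, columns=["symbol", "chromosome", "start", "end"])

    params = {
        "seed": seed, "beta": float(beta), "endpoint": endpoint,
        "causal_locus": causal_locus,
        "frequencies": {loc.name: loc.frequency for loc in loci},
        "n_target_per_stratum": n_target_per_stratum,
        "signal": asdict(signal), "ascertainment": info,
    }
    return TruthSet(loci=loci, segments=segments, z=z, phenotypes=phen,
                    report=report, transcripts=transcripts, params=params)
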