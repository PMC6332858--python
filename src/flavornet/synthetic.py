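"""Seeded synthetic ripening-transcriptome generator.

Emulates a 3-stage x 3-replicate fruit-ripening RNA-seq design: planted
co-expression modules follow stage-level log2-expression trajectories
(up, down-then-up, early-down by default), replicate libraries jitter
around the stage value, fragment counts are negative-binomial around
length- and depth-scaled FPKM means, and metabolite-like traits are
linear responses to module latents with Gaussian noise, floored at zero.

The default trait loadings mimic the magnitudes reported for ripening
apricot: sucrose rising from ~3 to ~124 mg/g, malic acid falling from
~35 to ~8 mg/g, plus volatile traits (beta-ionone, gamma-decalactone)
coupled to the other modules.

Randomness derives from one global seed split into named substreams
(truth / counts / traits), so each stage of the generator is
independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import CountMatrix

#: Default stage trajectories (log2 offsets per stage).  Two design
#: constraints: (1) with three stages the centred profile space is
#: two-dimensional, so the three shapes are placed 60 degrees apart
#: (pairwise |cos| = 0.5) -- an unsigned network cannot separate
#: mirror-image (up vs down) profiles, which are perfectly
#: anti-correlated; (2) the profiles are cyclic shifts of one multiset,
#: so the total planted transcript mass is stage-invariant in
#: expectation and module fold changes do not imprint a shared
#: compositional (library-size) trend on the background genes' FPKM.
DEFAULT_STAGE_PROFILES = (
    (-2.0, 0.0, 2.0),  # module 1: monotone up (sugar-accumulation-like)
    (0.0, 2.0, -2.0),  # module 2: up then down
    (2.0, -2.0, 0.0),  # module 3: down then up (early decline)
)

#: trait name -> (module index 1-based, slope, intercept, noise sd)
DEFAULT_TRAIT_LOADINGS = {
    "sucrose": (1, 30.33, 63.70, 12.0),  # ~3 -> ~124 mg/g across stages
    "malic_acid": (1, -6.675, 21.75, 2.7),  # ~35 -> ~8 mg/g
    "beta_ionone": (2, 48.0, 100.0, 19.0),  # relative units
    "gamma_decalactone": (3, -20.0, 45.0, 8.0),
}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study; defaults are the standard
    desk-scale benchmark (3 modules x 60 genes + 400 background genes,
    9 libraries)."""

    n_genes: int = 580
    module_sizes: tuple = (60, 60, 60)
    stage_profiles: tuple = DEFAULT_STAGE_PROFILES
    n_stages: int = 3
    n_reps: int = 3
    baseline_log2_fpkm_range: tuple = (2.0, 7.0)
    nb_dispersion: float = 0.05
    library_size_range: tuple = (2_000_000, 4_000_000)
    gene_length_range: tuple = (500, 3000)
    latent_jitter_sd: float = 0.15
    trait_loadings: dict = field(default_factory=lambda: dict(DEFAULT_TRAIT_LOADINGS))
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return self.n_stages * self.n_reps

    @property
    def library_ids(self) -> list[str]:
        return [f"S{s + 1}_R{r + 1}" for s in range(self.n_stages) for r in range(self.n_reps)]

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if any(s <= 0 for s in self.module_sizes):
            raise ValueError("module sizes must be positive")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError(
                f"module sizes sum to {sum(self.module_sizes)} > n_genes={self.n_genes}"
            )
        if len(self.stage_profiles) < len(self.module_sizes):
            raise ValueError("need one stage profile per module")
        if any(len(p) != self.n_stages for p in self.stage_profiles):
            raise ValueError(f"stage profiles must have length n_stages={self.n_stages}")
        if self.n_stages * self.n_reps < 4:
            raise ValueError("need at least 4 libraries")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        for name, rng in (
            ("baseline_log2_fpkm_range", self.baseline_log2_fpkm_range),
            ("library_size_range", self.library_size_range),
            ("gene_length_range", self.gene_length_range),
        ):
            if rng[1] <= rng[0]:
                raise ValueError(f"{name} must be a non-degenerate interval")
        n_modules = len(self.module_sizes)
        for trait, (m, _, _, sd) in self.trait_loadings.items():
            if not 1 <= m <= n_modules:
                raise ValueError(f"trait {trait!r} references unknown module {m}")
            if sd < 0:
                raise ValueError(f"trait {trait!r} has negative noise sd")


@dataclass
class SyntheticGroundTruth:
    """Planted structure: gene module labels (0 = background), the
    per-library latent value of each module, and the population
    module-trait correlation implied by each trait loading."""

    module_label_per_gene: pd.Series
    latent_per_module: pd.DataFrame  # libraries x modules
    trait_true_correlation: pd.Series


@dataclass
class SyntheticDataset:
    counts: CountMatrix
    traits: pd.DataFrame
    truth: SyntheticGroundTruth


_STREAM_KEYS = {"truth": 1, "counts": 2, "traits": 3, "null": 4}


def _stream(config_seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(config_seed, spawn_key=(_STREAM_KEYS[stream],))
    )


def make_ground_truth(config: SyntheticConfig) -> SyntheticGroundTruth:
    """Assign genes to modules and build per-library module latents.

    The first ``module_sizes[m]`` unassigned genes go to module m+1;
    the remainder are background (label 0).  Latents are the module's
    stage profile plus independent replicate jitter, centred to zero
    mean across libraries.
    """
    config.validate()
    rng = _stream(config.seed, "truth")
    labels = np.zeros(config.n_genes, dtype=int)
    start = 0
    for m, size in enumerate(config.module_sizes, start=1):
        labels[start : start + size] = m
        start += size
    gene_ids = pd.Index([f"g{i:05d}" for i in range(config.n_genes)], name="gene_id")

    libs = config.library_ids
    latents = {}
    for m in range(1, len(config.module_sizes) + 1):
        profile = np.repeat(config.stage_profiles[m - 1], config.n_reps)
        lat = profile + rng.normal(0.0, config.latent_jitter_sd, size=len(libs))
        latents[m] = lat - lat.mean()
    latent_df = pd.DataFrame(latents, index=pd.Index(libs, name="library_id"))
    latent_df.columns.name = "module"

    true_r = {}
    for trait, (m, slope, _, noise_sd) in config.trait_loadings.items():
        signal = abs(slope) * latent_df[m].std(ddof=1)
        denom = np.hypot(signal, noise_sd)
        true_r[trait] = float(np.sign(slope) * (signal / denom if denom > 0 else 1.0))

    return SyntheticGroundTruth(
        module_label_per_gene=pd.Series(labels, index=gene_ids, name="module_label"),
        latent_per_module=latent_df,
        trait_true_correlation=pd.Series(true_r, name="trait_true_correlation"),
    )


def _draw_counts(
    mean_fpkm: np.ndarray,
    lengths: np.ndarray,
    lib_sizes: np.ndarray,
    dispersion: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Negative-binomial counts around FPKM-implied means.

    mean_count[g, s] = FPKM[g, s] * length_bp[g] * lib_size[s] / 1e9;
    variance = mean + dispersion * mean**2 (Poisson when dispersion 0).
    """
    mu = mean_fpkm * lengths[:, None] * lib_sizes[None, :] / 1e9
    if dispersion == 0:
        return rng.poisson(mu)
    size = 1.0 / dispersion
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    p = size / (size + mu[pos])
    out[pos] = rng.negative_binomial(size, p)
    return out


def simulate_counts(truth: SyntheticGroundTruth, config: SyntheticConfig) -> CountMatrix:
    """Draw the count matrix implied by the planted structure.

    Expected FPKM of gene g in library s is 2**(baseline_g +
    latent_m(s)) for module genes (latent 0 for background).
    """
    config.validate()
    rng = _stream(config.seed, "counts")
    gene_ids = truth.module_label_per_gene.index
    libs = truth.latent_per_module.index

    lo, hi = config.baseline_log2_fpkm_range
    baseline = rng.uniform(lo, hi, size=len(gene_ids))
    lengths = rng.integers(
        config.gene_length_range[0], config.gene_length_range[1] + 1, size=len(gene_ids)
    )
    lib_sizes = rng.integers(
        config.library_size_range[0], config.library_size_range[1] + 1, size=len(libs)
    )

    latent = np.zeros((len(gene_ids), len(libs)))
    labels = truth.module_label_per_gene.to_numpy()
    for m in truth.latent_per_module.columns:
        latent[labels == m] = truth.latent_per_module[m].to_numpy()
    mean_fpkm = np.power(2.0, baseline[:, None] + latent)

    counts = _draw_counts(
        mean_fpkm, lengths.astype(float), lib_sizes.astype(float), config.nb_dispersion, rng
    )
    samples = pd.DataFrame(
        {
            "stage": [f"S{s + 1}" for s in range(config.n_stages) for _ in range(config.n_reps)],
            "replicate": [r + 1 for _ in range(config.n_stages) for r in range(config.n_reps)],
        },
        index=pd.Index(libs, name="library_id"),
    )
    return CountMatrix(
        counts=pd.DataFrame(counts, index=gene_ids, columns=libs),
        lengths=pd.Series(lengths, index=gene_ids, name="length_bp"),
        samples=samples,
    )


def simulate_traits(truth: SyntheticGroundTruth, config: SyntheticConfig) -> pd.DataFrame:
    """Metabolite-like trait table: linear in the module latent, noisy,
    floored at zero (concentrations cannot be negative)."""
    config.validate()
    rng = _stream(config.seed, "traits")
    libs = truth.latent_per_module.index
    cols = {}
    for trait, (m, slope, intercept, noise_sd) in config.trait_loadings.items():
        if m not in truth.latent_per_module.columns:
            raise ValueError(f"trait {trait!r} references unknown module {m}")
        vals = intercept + slope * truth.latent_per_module[m].to_numpy()
        vals = vals + rng.normal(0.0, noise_sd, size=len(libs))
        cols[trait] = np.maximum(vals, 0.0)
    return pd.DataFrame(cols, index=libs)


def simulate_dataset(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Ground truth + counts + traits in one call (shared seed)."""
    config = config or SyntheticConfig()
    truth = make_ground_truth(config)
    counts = simulate_counts(truth, config)
    traits = simulate_traits(truth, config)
    return SyntheticDataset(counts=counts, traits=traits, truth=truth)


def simulate_null_pair(
    n_genes: int, n1: int, n2: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Two count vectors with identical true relative abundances.

    Per-gene abundances are drawn once (exponential, normalised) and
    shared; counts are independent Poisson with expected totals N1 and
    N2.  Supports type-I-error calibration of the two-library test.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAM_KEYS["null"],)))
    w = rng.exponential(1.0, size=n_genes)
    p = w / w.sum()
    x = rng.poisson(n1 * p)
    y = rng.poisson(n2 * p)
    return x, y


def write_dataset(dataset: SyntheticDataset, outdir) -> dict:
    """Write counts/lengths/samples/traits/truth TSVs; returns paths."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.tsv",
        "lengths": out / "lengths.tsv",
        "samples": out / "samples.tsv",
        "traits": out / "traits.tsv",
        "truth": out / "truth.tsv",
    }
    cm = dataset.counts
    cm.counts.to_csv(paths["counts"], sep="\t", index_label="gene_id")
    cm.lengths.to_frame().to_csv(paths["lengths"], sep="\t", index_label="gene_id")
    cm.samples.to_csv(paths["samples"], sep="\t", index_label="library_id")
    dataset.traits.to_csv(paths["traits"], sep="\t", index_label="library_id")
    dataset.truth.module_label_per_gene.to_frame().to_csv(
        paths["truth"], sep="\t", index_label="gene_id"
    )
    return {k: str(v) for k, v in paths.items()}
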