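"""Seeded synthetic data with the statistical structure the pipeline assumes.

Three generators mirror the study design (two genotypes — wild type and a
late-ripening mutant — sampled at three ripening stages, one library each):

* Poisson read counts with a planted fraction of differentially expressed
  genes at a stated log2 effect (optionally negative-binomial, to probe the
  exact test's behaviour under overdispersion the Poisson model ignores);
* latent-factor coexpression modules — every gene in module m follows
  ``loading * f_m + noise`` for a standardized factor f_m — plus trait
  vectors tied linearly to chosen factors;
* TF domain-hit tables with controllable miss and decoy rates.

Every generator is deterministic given (seed, parameters) and returns the
ground truth alongside the data for recovery testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .de import CountMatrix
from .tf import DomainHit, default_family_rules

__all__ = [
    "SyntheticTruth",
    "generate_counts",
    "generate_coexpression",
    "generate_domain_hits",
    "default_design",
]

DEFAULT_N_GENES = 2000
DEFAULT_LIB_SIZE = 1_000_000
STAGES = (170, 190, 210)


class SimulationError(ValueError):
    """Raised on invalid generator parameters."""


def default_design() -> list[str]:
    """Sample ids for the 2-genotype x 3-stage layout, e.g. WT170 .. MT210."""
    return [f"{g}{s}" for g in ("WT", "MT") for s in STAGES]


@dataclass
class SyntheticTruth:
    """Planted structure of a synthetic dataset, keyed by the RNG seed."""

    seed: int
    params: dict = field(default_factory=dict)
    de_effects: dict[str, float] = field(default_factory=dict)  # gene -> signed log2 effect
    module_of: dict[str, str] = field(default_factory=dict)  # gene -> planted module
    loading: float | None = None
    trait_links: dict[str, str] = field(default_factory=dict)  # trait -> module
    families: dict[str, str] = field(default_factory=dict)  # gene -> TF family
    missed_genes: list[str] = field(default_factory=list)
    decoy_genes: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def generate_counts(
    n_genes: int = DEFAULT_N_GENES,
    design: list[str] | None = None,
    lib_sizes: int | dict[str, int] = DEFAULT_LIB_SIZE,
    de_fraction: float = 0.1,
    effect_log2: float = 2.0,
    seed: int = 0,
    base_rate_log_mean: float = 3.0,
    base_rate_log_sd: float = 1.2,
    length_range: tuple[int, int] = (200, 5000),
    nb_dispersion: float | None = None,
) -> tuple[CountMatrix, SyntheticTruth]:
    """Poisson count matrix with planted genotype differential expression.

    Gene g in sample s draws ``x ~ Poisson(lambda_g * m_gs * N_s / 1e6)``
    where lambda_g (expected reads per million) is log-normal with the
    given log-mean/sd, and the multiplier m_gs is ``2**(+-effect_log2)``
    for planted DE genes in mutant samples and 1 otherwise (sign chosen at
    random per gene).  Gene lengths are sampled uniformly from
    `length_range` and recorded.  With `nb_dispersion` set, counts become
    negative-binomial via a per-observation Gamma rate multiplier of that
    1/size parameter — deliberately violating the exact test's Poisson
    assumption.
    """
    if not 0 <= de_fraction <= 1:
        raise SimulationError(f"de_fraction must be in [0,1], got {de_fraction}")
    design = list(design) if design is not None else default_design()
    if isinstance(lib_sizes, dict):
        libs = pd.Series(lib_sizes).reindex(design)
        if libs.isna().any():
            raise SimulationError("lib_sizes missing some design samples")
    else:
        libs = pd.Series(int(lib_sizes), index=design)
    if (libs <= 0).any():
        raise SimulationError("library sizes must be positive")

    rng = np.random.default_rng(seed)
    genes = [f"gene{i:05d}" for i in range(n_genes)]
    lam = rng.lognormal(base_rate_log_mean, base_rate_log_sd, n_genes)
    lengths = rng.integers(length_range[0], length_range[1] + 1, n_genes)
    n_de = int(round(de_fraction * n_genes))
    de_idx = rng.choice(n_genes, n_de, replace=False)
    signs = rng.choice([-1.0, 1.0], n_de)

    mult = np.ones((n_genes, len(design)))
    is_mt = np.array([s.startswith("MT") for s in design])
    for i, s in zip(de_idx, signs):
        mult[i, is_mt] = 2.0 ** (s * effect_log2)

    rate = lam[:, None] * mult * libs.to_numpy()[None, :] / 1e6
    if nb_dispersion is not None:
        if nb_dispersion <= 0:
            raise SimulationError("nb_dispersion must be positive")
        rate = rate * rng.gamma(1.0 / nb_dispersion, nb_dispersion, rate.shape)
    counts = rng.poisson(rate)

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=design),
        library_sizes=libs,
        gene_lengths=pd.Series(lengths, index=genes, name="length"),
    )
    truth = SyntheticTruth(
        seed=int(seed),
        params={
            "n_genes": n_genes, "design": design,
            "lib_sizes": {k: int(v) for k, v in libs.items()},
            "de_fraction": de_fraction, "effect_log2": effect_log2,
            "base_rate_log_mean": base_rate_log_mean,
            "base_rate_log_sd": base_rate_log_sd,
            "nb_dispersion": nb_dispersion,
        },
        de_effects={genes[i]: float(s * effect_log2) for i, s in zip(de_idx, signs)},
    )
    return cm, truth


def generate_coexpression(
    n_modules: int = 5,
    sizes: int | list[int] = 50,
    loading: float = 0.9,
    noise_sd: float | None = None,
    n_background: int = 100,
    n_samples: int = 6,
    trait_links: dict[str, int] | None = None,
    trait_noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Latent-factor expression with planted modules and linked traits.

    Module m has a standardized factor f_m over samples; each member gene
    is ``loading * f_m + N(0, noise_sd)`` with noise_sd defaulting to
    ``sqrt(1 - loading**2)`` so genes have unit variance and within-module
    correlation ~ loading**2.  Background genes are pure noise.  Each trait
    in `trait_links` (name -> module index) is its module's factor plus
    N(0, trait_noise_sd) noise.  Returns (expression genes x samples,
    traits samples x traits, truth).  Values are on a log-expression-like
    standardized scale.
    """
    if not 0 < loading <= 1:
        raise SimulationError(f"loading must be in (0, 1], got {loading}")
    sizes = [sizes] * n_modules if np.isscalar(sizes) else list(sizes)
    if len(sizes) != n_modules or any(s < 2 for s in sizes):
        raise SimulationError("need one size >= 2 per module")
    if noise_sd is None:
        noise_sd = float(np.sqrt(1.0 - loading**2))
    rng = np.random.default_rng(seed)
    samples = default_design() if n_samples == 6 else [
        f"S{j + 1:02d}" for j in range(n_samples)
    ]
    factors = rng.standard_normal((n_modules, n_samples))
    factors = (factors - factors.mean(1, keepdims=True)) / factors.std(1, ddof=1, keepdims=True)

    rows, ids, module_of = [], [], {}
    for m, size in enumerate(sizes):
        name = f"M{m + 1}"
        for g in range(size):
            gid = f"{name}_g{g + 1:03d}"
            ids.append(gid)
            module_of[gid] = name
            rows.append(loading * factors[m] + rng.normal(0, noise_sd, n_samples))
    for g in range(n_background):
        gid = f"bg_g{g + 1:03d}"
        ids.append(gid)
        rows.append(rng.standard_normal(n_samples))
    expr = pd.DataFrame(np.array(rows), index=ids, columns=samples)

    trait_links = trait_links or {}
    traits = pd.DataFrame(index=pd.Index(samples, name="sample"))
    links = {}
    for trait, m in trait_links.items():
        if not 0 <= m < n_modules:
            raise SimulationError(f"trait {trait!r} links to unknown module {m}")
        traits[trait] = factors[m] + rng.normal(0, trait_noise_sd, n_samples)
        links[trait] = f"M{m + 1}"

    truth = SyntheticTruth(
        seed=int(seed),
        params={
            "n_modules": n_modules, "sizes": sizes, "loading": loading,
            "noise_sd": noise_sd, "n_background": n_background,
            "n_samples": n_samples, "trait_noise_sd": trait_noise_sd,
        },
        module_of=module_of,
        loading=loading,
        trait_links=links,
    )
    return expr, traits, truth


def generate_domain_hits(
    families: dict[str, str],
    miss_rate: float = 0.0,
    decoy_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[DomainHit], SyntheticTruth]:
    """Domain-hit table for genes with known planted TF families.

    Each TF gene emits a hit to (one required model of) its family with
    e-value sampled below the 1e-10 assignment cutoff, except a `miss_rate`
    fraction that emit nothing; a `decoy_rate` fraction of genes emit an
    extra hit with e-value above the cutoff, which assignment must ignore.
    """
    if not (0 <= miss_rate < 1 and 0 <= decoy_rate < 1):
        raise SimulationError("miss_rate and decoy_rate must be in [0, 1)")
    model_of = {r.family_name: sorted(r.required_models)[0]
                for r in default_family_rules()}
    unknown = set(families.values()) - set(model_of)
    if unknown:
        raise SimulationError(f"no default rule for families: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    hits, missed, decoys = [], [], []
    all_models = sorted(model_of.values())
    for gene, fam in sorted(families.items()):
        if rng.random() < miss_rate:
            missed.append(gene)
        else:
            e = 10.0 ** rng.uniform(-50, -11)
            hits.append(DomainHit(gene, model_of[fam], e, float(rng.uniform(50, 300))))
        if rng.random() < decoy_rate:
            e = 10.0 ** rng.uniform(-9, -1)  # above cutoff: must be ignored
            model = all_models[rng.integers(len(all_models))]
            hits.append(DomainHit(gene, model, e, float(rng.uniform(5, 40))))
            decoys.append(gene)
    truth = SyntheticTruth(
        seed=int(seed),
        params={"miss_rate": miss_rate, "decoy_rate": decoy_rate},
        families=dict(families),
        missed_genes=missed,
        decoy_genes=decoys,
    )
    return hits, truth
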