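"""Synthetic 16S-style data with planted co-abundance structure.

The generator emulates the statistical shape of an amplicon survey of a
long-lived human cohort: ~135 stool samples, a few thousand OTU columns,
blocks of OTUs driven by shared latent factors (the "modules" a weighted
co-abundance network should recover), one block whose factor tracks a binary
longevity indicator, genus annotations arranged so each planted block maps to
nameable genera, plus small companion tables (strain probiotic indicators
with a single common factor, qPCR Ct values with known fold changes).

Counts follow a lognormal-Poisson mixture by default: a latent Gaussian
factor model on the log scale, exponentiated into Poisson rates. This gives
overdispersed, correlated, zero-inflated integer counts with two knobs that
matter (factor loading and baseline abundance) and nothing else. A
negative-binomial alternative adds a gamma stage controlled by
``dispersion``. Everything is driven by one ``numpy`` Generator so a design
plus a seed reproduces byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from longicore.abundance_io import RANKS, AbundanceTable

#: The five core genera the discovery pipeline is expected to surface.
CORE_GENERA = (
    "Alistipes",
    "Bacteroides",
    "Blautia",
    "Lachnospiraceae NK4A136 group",
    "Lactobacillus",
)

_PHYLA = ("Firmicutes", "Bacteroidetes", "Proteobacteria", "Actinobacteria")
# genus -> phylum for the aliased core genera, so phylum ratios are meaningful
_CORE_PHYLUM = {
    "Alistipes": "Bacteroidetes",
    "Bacteroides": "Bacteroidetes",
    "Blautia": "Firmicutes",
    "Lachnospiraceae NK4A136 group": "Firmicutes",
    "Lactobacillus": "Firmicutes",
}

BACKGROUND = "background"


class InvalidDesignError(ValueError):
    """Raised when a synthetic design violates its invariants."""


@dataclass
class SyntheticDesign:
    """Parameters of one synthetic cohort.

    modules: per planted block, (size, latent_corr) where latent_corr in
        (0, 1] is the nominal loading of member OTUs on the block factor.
        Within a block, loadings decay linearly from latent_corr down to
        ``loading_floor * latent_corr`` so the leading members are the
        strongest-coupled (and hence the expected network hubs).
    trait_module_index: which block's factor the binary longevity trait
        follows; None plants no association.
    trait_effect: target point-biserial correlation between the binary trait
        and the chosen block factor (0 = null design).
    discriminative_genera: extra (genus, standardized mean difference)
        location shifts between trait groups, applied on the latent log scale.
    """

    n_samples: int = 135
    n_otus: int = 2000
    modules: tuple = ((60, 0.8), (45, 0.7), (35, 0.6))
    trait_module_index: int | None = 0
    trait_effect: float = 0.5
    discriminative_genera: tuple = ()
    count_model: str = "lognormal"
    dispersion: float = 0.5
    seed: int = 0
    genera_per_module: int = 5
    core_genus_alias: bool = True
    loading_floor: float = 0.7
    log_sigma: float = 1.0
    background_zero_range: tuple = (0.6, 0.9)
    # share of background OTUs given a long-tailed abundant baseline so the
    # per-sample total is not dominated by the planted blocks (otherwise
    # closure to relative abundance would cancel their shared variation)
    background_abundant_fraction: float = 0.2

    def validate(self) -> None:
        if self.n_samples < 4:
            raise InvalidDesignError("need at least 4 samples")
        if sum(size for size, _ in self.modules) > self.n_otus:
            raise InvalidDesignError("module sizes exceed n_otus")
        for size, corr in self.modules:
            if size < 2:
                raise InvalidDesignError("module size must be >= 2")
            if not 0 < corr <= 1:
                raise InvalidDesignError("latent_corr must be in (0, 1]")
        if self.trait_module_index is not None and not (
            0 <= self.trait_module_index < len(self.modules)
        ):
            raise InvalidDesignError("trait_module_index out of range")
        if not -1 <= self.trait_effect <= 1:
            raise InvalidDesignError("trait_effect must be in [-1, 1]")
        if self.count_model not in ("lognormal", "negative_binomial"):
            raise InvalidDesignError(f"unknown count model {self.count_model!r}")
        if self.dispersion <= 0:
            raise InvalidDesignError("dispersion must be positive")

    def to_config(self) -> str:
        """Flat key = value text serialization for provenance."""
        lines = []
        for key, value in asdict(self).items():
            lines.append(f"{key} = {value!r}")
        return "\n".join(lines) + "\n"


def _module_genera(design: SyntheticDesign) -> list[list[str]]:
    """Genus names for each planted module, optionally aliasing the trait
    module's genera to the five core genus names."""
    out = []
    counter = 1
    for m, (size, _) in enumerate(design.modules):
        n_gen = min(design.genera_per_module, size)
        names = [f"Genus_{counter + j:03d}" for j in range(n_gen)]
        counter += n_gen
        out.append(names)
    if design.core_genus_alias and design.trait_module_index is not None:
        tm = design.trait_module_index
        aliased = list(CORE_GENERA[: len(out[tm])])
        while len(aliased) < len(out[tm]):
            aliased.append(out[tm][len(aliased)])
        out[tm] = aliased
    return out


def generate_abundance(design: SyntheticDesign):
    """Generate (AbundanceTable, trait table, OTU -> module ground truth).

    The binary longevity trait is obtained by median-thresholding a Gaussian
    latent correlated with the chosen module factor; the latent correlation is
    inflated by 1/sqrt(2/pi) so the *binary* trait's point-biserial
    correlation with the factor lands near ``trait_effect``.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    n, p = design.n_samples, design.n_otus
    n_mod = len(design.modules)

    factors = rng.standard_normal((n_mod, n))

    # binary trait
    if design.trait_module_index is not None and design.trait_effect != 0:
        target = abs(design.trait_effect)
        rho = min(1.0, target / np.sqrt(2.0 / np.pi))
        eps = rng.standard_normal(n)
        latent = rho * factors[design.trait_module_index] + np.sqrt(1 - rho**2) * eps
        trait = (latent > np.median(latent)).astype(int)
        if design.trait_effect < 0:
            trait = 1 - trait
    else:
        trait = np.zeros(n, dtype=int)
        trait[rng.permutation(n)[: n // 2]] = 1

    # latent log-scale profiles
    z = np.empty((n, p))
    membership = np.full(p, BACKGROUND, dtype=object)
    genus = np.empty(p, dtype=object)
    phylum = np.empty(p, dtype=object)
    module_genera = _module_genera(design)

    pos = 0
    for m, (size, corr) in enumerate(design.modules):
        loadings = np.linspace(corr, design.loading_floor * corr, size)
        noise = rng.standard_normal((n, size))
        block = loadings * factors[m][:, None] + np.sqrt(1 - loadings**2) * noise
        z[:, pos : pos + size] = block
        membership[pos : pos + size] = f"M{m}"
        names = module_genera[m]
        for j in range(size):
            g = names[j % len(names)]
            genus[pos + j] = g
            phylum[pos + j] = _CORE_PHYLUM.get(g, _PHYLA[m % len(_PHYLA)])
        pos += size

    n_bg = p - pos
    z[:, pos:] = rng.standard_normal((n, n_bg))
    for j in range(n_bg):
        genus[pos + j] = f"Genus_B{j // 20 + 1:03d}"
        phylum[pos + j] = _PHYLA[(j // 20) % len(_PHYLA)]

    # planted group differences for selected genera
    centred = trait - trait.mean()
    for gname, effect in design.discriminative_genera:
        cols = np.flatnonzero(genus == gname)
        if len(cols) == 0:
            raise InvalidDesignError(f"discriminative genus {gname!r} not present")
        z[:, cols] += effect * centred[:, None]

    # baseline abundances: planted OTUs abundant enough that the Poisson
    # counting layer does not wash out the designed correlations
    # (var(log N) ~ sigma^2 + 1/lambda); background mostly sparse, with an
    # abundant long-tailed subset carrying the bulk of the sample totals
    base = np.empty(p)
    base[:pos] = np.exp(rng.uniform(np.log(20.0), np.log(150.0), pos))
    lo, hi = design.background_zero_range
    target_zero = rng.uniform(lo, hi, n_bg)
    base[pos:] = -np.log(target_zero)
    frac = design.background_abundant_fraction
    if frac > 0 and n_bg > 0:
        step = max(1, int(round(1.0 / frac)))
        abundant = np.arange(n_bg) % step == 0
        base[pos:][abundant] = np.exp(
            rng.uniform(np.log(10.0), np.log(800.0), int(abundant.sum()))
        )

    lam = base[None, :] * np.exp(
        design.log_sigma * z - 0.5 * design.log_sigma**2
    )
    if design.count_model == "negative_binomial":
        shape = 1.0 / design.dispersion
        lam = rng.gamma(shape, lam * design.dispersion)
    counts = rng.poisson(lam).astype(float)

    otu_ids = [f"OTU_{j + 1:05d}" for j in range(p)]
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    counts_df = pd.DataFrame(counts, index=sample_ids, columns=otu_ids)

    taxonomy = pd.DataFrame("", index=otu_ids, columns=list(RANKS))
    taxonomy["kingdom"] = "Bacteria"
    taxonomy["phylum"] = phylum
    taxonomy["genus"] = genus

    age = np.where(trait == 1, rng.integers(90, 110, n), rng.integers(55, 90, n))
    traits = pd.DataFrame(
        {
            "age": age,
            "sex": rng.choice(["F", "M"], n),
            "group": np.where(trait == 1, "LG", "YG"),
            "longevity": trait,
        },
        index=sample_ids,
    )
    ground_truth = dict(zip(otu_ids, membership))
    table = AbundanceTable(counts=counts_df, taxonomy=taxonomy)
    return table, traits, ground_truth


def generate_strain_properties(
    n_strains: int = 14,
    factor_loadings=(1.0, 1.0, 1.0),
    noise_sd: float = 0.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Strain x three-probiotic-indicator table from a single common factor.

    Indicators (GI-transit survival, self-aggregation, hydrophobicity, all in
    percent) share one latent "robustness" factor, so for small noise_sd their
    correlation matrix approaches rank one and KMO approaches 1. Strains are
    labelled CE (centenarian-derived) for the first half and GE otherwise.
    """
    if n_strains < 3:
        raise ValueError("need at least 3 strains for downstream PCA")
    loadings = np.asarray(factor_loadings, dtype=float)
    if loadings.shape != (3,):
        raise ValueError("factor_loadings must have length 3")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    g = rng.standard_normal(n_strains)
    raw = loadings[None, :] * g[:, None] + noise_sd * rng.standard_normal(
        (n_strains, 3)
    )
    # map to plausible percentage scales
    centre = np.array([55.0, 40.0, 50.0])
    spread = np.array([15.0, 12.0, 18.0])
    pct = np.clip(centre + spread * raw, 0.0, 100.0)
    ids = [f"STR{i + 1:02d}" for i in range(n_strains)]
    source = ["CE" if i < n_strains // 2 else "GE" for i in range(n_strains)]
    return pd.DataFrame(
        {
            "source": source,
            "gi_survival": pct[:, 0],
            "self_aggregation": pct[:, 1],
            "hydrophobicity": pct[:, 2],
        },
        index=pd.Index(ids, name="strain"),
    )


def generate_ct_table(
    n_per_group: int = 6,
    true_fold_changes=None,
    ct_noise_sd: float = 0.2,
    seed: int = 0,
    reference_ct: float = 16.0,
) -> pd.DataFrame:
    """qPCR Ct table with known fold changes between treatment and control.

    The reference gene (total bacteria) sits at a fixed baseline; each target
    genus has its own control baseline, and the treatment group's target Ct is
    shifted down by log2(fold change), so 2^-ddCt recovers the planted folds.
    """
    if true_fold_changes is None:
        true_fold_changes = {g: 2.0 for g in CORE_GENERA}
    for g, fc in true_fold_changes.items():
        if fc <= 0:
            raise ValueError(f"fold change for {g!r} must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for t_idx, (target, fold) in enumerate(sorted(true_fold_changes.items())):
        baseline = 24.0 + 1.5 * t_idx
        for group, shift in (("control", 0.0), ("treatment", -np.log2(fold))):
            for i in range(n_per_group):
                ct_t = baseline + shift + ct_noise_sd * rng.standard_normal()
                rows.append(
                    {
                        "sample": f"{group[:4]}{i + 1:02d}",
                        "group": group,
                        "target": target,
                        "ct_target": ct_t,
                        "ct_reference": reference_ct,
                    }
                )
    return pd.DataFrame(rows)
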