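"""Synthetic two-cohort tumor-microbiome survival data with known truth.

Emulates the structure of two resected early-stage PDAC cohorts (a larger
and a smaller one, defaults 140 and 63 samples): compositional species
counts with cohort-level batch shifts, clinical covariates, heavily censored
overall-survival (OS) and relapse-free-survival (RFS) outcomes generated
from a proportional-hazards model on the clr scale of the true composition,
and a CIBERSORT-style 22-column immune-fraction table optionally linked to
causal taxa.

The generative model, per cohort c and sample s:

* latent log-abundance  a_{s,t} = mu_t + b_{c,t} + eps_{s,t} with
  mu_t ~ N(0, 1.5), batch shift b_{c,t} ~ N(0, batch_shift_sd),
  eps ~ N(0, 1); true composition p_s = softmax(a_s);
* counts ~ Multinomial(depth_s, p_s), depth_s log-uniform in [5e3, 5e4];
* linear predictor eta_s = sum_k beta_k clr(p_s)_k + covariate effects;
  death time T ~ Exponential(rate lambda exp(eta)), relapse time with a
  proportionally larger hazard, RFS time = min(relapse, death) so
  rfs_time <= os_time always;
* independent uniform censoring on [0, c] with c solved numerically so the
  expected OS censoring fraction matches ``censor_rate_target``.

Causal taxa are drawn from the more abundant half of the taxon pool so that
configured effects act on species that survive prevalence filtering.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from microsurv import io as msio

__all__ = [
    "SimulationConfig", "SyntheticTruth", "CohortBundle",
    "simulate_cohorts", "simulate_survival", "simulate_immune",
    "simulate_expression", "write_bundles", "IMMUNE_CELL_TYPES",
]

# the 22 LM22-style immune cell types of CIBERSORT output
IMMUNE_CELL_TYPES = (
    "B cells naive", "B cells memory", "Plasma cells",
    "T cells CD8", "T cells CD4 naive", "T cells CD4 memory resting",
    "T cells CD4 memory activated", "T cells follicular helper",
    "T cells regulatory (Tregs)", "T cells gamma delta",
    "NK cells resting", "NK cells activated", "Monocytes",
    "Macrophages M0", "Macrophages M1", "Macrophages M2",
    "Dendritic cells resting", "Dendritic cells activated",
    "Mast cells resting", "Mast cells activated",
    "Eosinophils", "Neutrophils",
)

DEFAULT_COVARIATE_EFFECTS = {
    # log-HR per unit; age per year (centered at 66)
    "age": 0.03,
    "sex_male": -0.1,
    "stage_iib": 0.55,
    "smoking_current": 0.06,
    "smoking_former": -0.16,
}

_SMOKING_LEVELS = ("Never", "Current", "Former", "Not reported")
_SMOKING_PROBS = (0.373, 0.114, 0.383, 0.13)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the two-cohort generator; defaults are the study conditions."""

    n_per_cohort: tuple[int, int] = (140, 63)
    n_taxa: int = 400
    n_causal: int = 10
    true_log_hr: float = 0.5          # magnitude; signs alternate
    baseline_hazard: tuple[float, float] = (0.045, 0.045)  # per month
    relapse_hazard_ratio: float = 1.5
    censor_rate_target: float = 0.40  # OS censoring fraction
    batch_shift_sd: float = 1.0
    immune_link_strength: float = 1.0
    depth_range: tuple[float, float] = (5e3, 5e4)
    covariate_effects: dict = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS))
    seed: int = 0

    def __post_init__(self):
        if self.n_causal > self.n_taxa:
            raise ValueError("n_causal exceeds n_taxa")
        if any(h <= 0 for h in self.baseline_hazard):
            raise ValueError("baseline hazards must be positive")
        if not 0 <= self.censor_rate_target < 1:
            raise ValueError("censor_rate_target must lie in [0, 1)")
        if self.batch_shift_sd < 0:
            raise ValueError("batch_shift_sd must be non-negative")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of one simulated dataset."""

    causal_taxa: tuple[str, ...]
    beta_true: dict[str, float]       # log-HR per clr unit
    covariate_effects: dict[str, float]
    immune_links: dict[str, str]      # causal taxon -> linked cell type
    seed: int

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


@dataclass
class CohortBundle:
    """One cohort's counts, metadata and survival outcomes."""

    cohort_id: str
    counts: pd.DataFrame              # samples x taxa, non-negative ints
    metadata: pd.DataFrame            # age/sex/stage/smoking + outcomes

    def __post_init__(self):
        if not self.counts.index.equals(self.metadata.index):
            raise ValueError("counts and metadata sample ids disagree")
        if (self.metadata["rfs_time"] > self.metadata["os_time"] + 1e-9).any():
            raise ValueError("rfs_time exceeds os_time")


def _softmax(a):
    z = a - a.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _clr_rows(p):
    logp = np.log(p)
    return logp - logp.mean(axis=1, keepdims=True)


def _calibrate_censor_bound(latent_times, target):
    """Solve for c with E[fraction censored under U(0,c)] == target."""
    t = np.asarray(latent_times, dtype=float)

    def frac(c):
        return np.minimum(t / c, 1.0).mean() - target

    hi = 10.0 * t.max() / max(target, 1e-6)
    lo = 1e-9
    if frac(hi) > 0:  # target unreachably low for these times
        return hi
    return brentq(frac, lo, hi)


def simulate_survival(eta, baseline_hazard, censor_rate_target, rng):
    """Draw (time, event) from an exponential-baseline PH model.

    T = -log(U)/(lambda * exp(eta)) with U ~ Uniform(0,1); censoring is
    independent uniform on [0, c] with c calibrated to the target censoring
    fraction (no censoring if the target is 0).
    """
    if baseline_hazard <= 0:
        raise ValueError("baseline hazard must be positive")
    eta = np.asarray(eta, dtype=float)
    u = rng.uniform(size=eta.shape)
    latent = -np.log(u) / (baseline_hazard * np.exp(eta))
    if censor_rate_target == 0:
        return latent, np.ones(eta.shape, dtype=int)
    c = _calibrate_censor_bound(latent, censor_rate_target)
    censor = rng.uniform(0, c, size=eta.shape)
    event = (latent <= censor).astype(int)
    return np.minimum(latent, censor), event


def _simulate_covariates(n, rng):
    age = np.clip(rng.normal(66, 10, n), 34, 90).round(1)
    sex = np.where(rng.uniform(size=n) < 0.55, "Male", "Female")
    stage = np.where(rng.uniform(size=n) < 0.70, "IIB", "I/IIA")
    smoking = rng.choice(_SMOKING_LEVELS, size=n,
                         p=np.asarray(_SMOKING_PROBS) / sum(_SMOKING_PROBS))
    return pd.DataFrame({"age": age, "sex": sex, "stage": stage,
                         "smoking": smoking})


def _covariate_eta(meta, effects):
    eta = effects.get("age", 0.0) * (meta["age"].to_numpy() - 66.0)
    eta = eta + effects.get("sex_male", 0.0) * (meta["sex"] == "Male")
    eta = eta + effects.get("stage_iib", 0.0) * (meta["stage"] == "IIB")
    eta = eta + effects.get("smoking_current", 0.0) * (
        meta["smoking"] == "Current")
    eta = eta + effects.get("smoking_former", 0.0) * (
        meta["smoking"] == "Former")
    return np.asarray(eta, dtype=float)


def simulate_cohorts(config: SimulationConfig):
    """Generate the two cohorts and their ground truth.

    Returns ``(bundles, truth)`` with one :class:`CohortBundle` per entry of
    ``config.n_per_cohort``.  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    taxa = np.array([f"Species_{i:04d}" for i in range(config.n_taxa)])
    mu = rng.normal(0.0, 1.5, config.n_taxa)

    # causal taxa drawn from the abundant half so effects are observable
    abundant = np.argsort(mu)[config.n_taxa // 2:]
    causal_idx = rng.choice(abundant, size=config.n_causal, replace=False)
    signs = np.where(np.arange(config.n_causal) % 2 == 0, 1.0, -1.0)
    beta = dict(zip(taxa[causal_idx],
                    (signs * config.true_log_hr).tolist()))
    immune_links = {taxon: IMMUNE_CELL_TYPES[k % len(IMMUNE_CELL_TYPES)]
                    for k, taxon in enumerate(taxa[causal_idx])}
    truth = SyntheticTruth(
        causal_taxa=tuple(taxa[causal_idx]),
        beta_true=beta,
        covariate_effects=dict(config.covariate_effects),
        immune_links=immune_links,
        seed=config.seed,
    )

    bundles = []
    for c, n in enumerate(config.n_per_cohort):
        batch = rng.normal(0.0, config.batch_shift_sd, config.n_taxa)
        latent = mu + batch + rng.normal(0.0, 1.0, (n, config.n_taxa))
        comp = _softmax(latent)
        depth = np.exp(rng.uniform(np.log(config.depth_range[0]),
                                   np.log(config.depth_range[1]), n))
        counts = np.vstack([rng.multinomial(int(d), p)
                            for d, p in zip(depth, comp)])

        meta = _simulate_covariates(n, rng)
        meta.index = pd.Index(
            [f"C{c + 1}_S{j:03d}" for j in range(n)], name="sample")
        clr_true = _clr_rows(comp)
        eta = _covariate_eta(meta, config.covariate_effects)
        eta = eta + clr_true[:, causal_idx] @ (
            signs * config.true_log_hr)
        eta = eta - eta.mean()

        lam = config.baseline_hazard[c]
        u_death = rng.uniform(size=n)
        death = -np.log(u_death) / (lam * np.exp(eta))
        u_rel = rng.uniform(size=n)
        relapse = -np.log(u_rel) / (
            lam * config.relapse_hazard_ratio * np.exp(eta))
        rfs_latent = np.minimum(relapse, death)
        if config.censor_rate_target > 0:
            cbound = _calibrate_censor_bound(death, config.censor_rate_target)
            censor = rng.uniform(0, cbound, size=n)
        else:
            censor = np.full(n, np.inf)
        meta["os_time"] = np.minimum(death, censor)
        meta["os_event"] = (death <= censor).astype(int)
        meta["rfs_time"] = np.minimum(rfs_latent, censor)
        meta["rfs_event"] = (rfs_latent <= censor).astype(int)
        meta.insert(0, "cohort", f"cohort{c + 1}")

        counts_df = pd.DataFrame(counts, index=meta.index, columns=taxa)
        counts_df.columns.name = "taxon"
        bundles.append(CohortBundle(f"cohort{c + 1}", counts_df, meta))
    return bundles, truth


def simulate_immune(clr_matrix: pd.DataFrame, truth: SyntheticTruth,
                    config: SimulationConfig, rng=None) -> pd.DataFrame:
    """Dirichlet immune-cell fractions, optionally linked to causal taxa.

    Each linked cell type's Dirichlet concentration is multiplied by
    ``exp(immune_link_strength * z)`` where z is the standardized clr value
    of its linked causal taxon, so a positive link strength makes that cell
    type's fraction increase with the taxon's relative abundance.
    Rows sum to one exactly.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n = clr_matrix.shape[0]
    base = np.linspace(3.0, 1.0, len(IMMUNE_CELL_TYPES))  # mildly uneven mix
    alpha = np.tile(base, (n, 1))
    if config.immune_link_strength != 0:
        for taxon, cell in truth.immune_links.items():
            if taxon not in clr_matrix.columns:
                continue
            z = clr_matrix[taxon].to_numpy()
            z = (z - z.mean()) / max(z.std(), 1e-12)
            j = IMMUNE_CELL_TYPES.index(cell)
            alpha[:, j] *= np.exp(config.immune_link_strength * z)
    fractions = np.vstack([rng.dirichlet(a) for a in alpha])
    return pd.DataFrame(fractions, index=clr_matrix.index,
                        columns=list(IMMUNE_CELL_TYPES))


def simulate_expression(clr_matrix: pd.DataFrame, truth: SyntheticTruth,
                        n_genes: int = 60, link_strength: float = 0.8,
                        rng=None):
    """Gaussian gene-expression matrix with some genes tied to causal taxa.

    The first ``len(causal_taxa)`` genes each track one causal taxon's
    standardized clr value with the given link strength; the rest are
    independent noise.  Returns ``(expression samples x genes, linked)``
    where ``linked`` maps gene -> causal taxon.
    """
    if rng is None:
        rng = np.random.default_rng(truth.seed + 2)
    n = clr_matrix.shape[0]
    genes = [f"GENE{g:03d}" for g in range(n_genes)]
    expr = rng.normal(size=(n, n_genes))
    linked = {}
    for g, taxon in enumerate(truth.causal_taxa):
        if g >= n_genes or taxon not in clr_matrix.columns:
            break
        z = clr_matrix[taxon].to_numpy()
        z = (z - z.mean()) / max(z.std(), 1e-12)
        expr[:, g] = link_strength * z + np.sqrt(1 - min(link_strength**2, 1)
                                                 ) * rng.normal(size=n)
        linked[genes[g]] = taxon
    return (pd.DataFrame(expr, index=clr_matrix.index, columns=genes),
            linked)


def write_bundles(bundles, truth: SyntheticTruth, outdir) -> dict:
    """Write each cohort's counts/metadata TSVs and the truth JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for b in bundles:
        cpath = outdir / f"{b.cohort_id}_counts.tsv"
        mpath = outdir / f"{b.cohort_id}_metadata.tsv"
        msio.write_counts(b.counts, cpath)
        msio.write_metadata(b.metadata, mpath)
        paths[b.cohort_id] = {"counts": str(cpath), "metadata": str(mpath)}
    tpath = outdir / "truth.json"
    tpath.write_text(truth.to_json())
    paths["truth"] = str(tpath)
    return paths
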