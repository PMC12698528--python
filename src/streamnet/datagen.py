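"""Synthetic OTU tables with a factorial mesocosm design and planted structure.

The generator emulates a Before-After-Control-Impact stream-mesocosm
experiment: mesocosms crossed over habitat-heterogeneity and hydrology
treatments, arranged in spatial blocks, sampled on several days. Counts are
drawn through a Gaussian copula — a latent multivariate normal with a
block-structured correlation matrix (the planted co-occurrence modules) is
pushed through negative-binomial marginal quantile functions, then rescaled
to a fixed sequencing depth with a multinomial draw, which makes the data
compositional like real amplicon libraries.

Treatment effects are generative and directional: during the drought phase,
each taxon in a drying mesocosm is independently zeroed with probability
``p_loss_drying`` (richness goes down) and the surviving mean abundances are
flattened by raising them to ``evenness_exponent`` < 1 (evenness, hence
Shannon diversity, goes up). After flow resumption the drying parameters are
mixed back toward the control values by ``recovery_mix``.

The copula construction matters because the downstream edge screen is
rank-based: Spearman correlation is invariant to the monotone marginal
transform, so the planted latent correlations survive into the counts and
the ground-truth edge set (pairs with |latent correlation| >= the truth
threshold) is recoverable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .profiles import CountTable

__all__ = [
    "DEFAULT_DAYS",
    "TruthSpec",
    "generate_design",
    "make_truth",
    "generate_counts",
    "evaluate_edge_recovery",
    "simulate_experiment",
]

DEFAULT_DAYS = (23, 26, 38, 61)

_HABITAT_NAMES = ("low", "medium", "high")
_HYDROLOGY_NAMES = ("control", "drying")


@dataclass
class TruthSpec:
    """Ground truth behind a synthetic count table.

    Attributes
    ----------
    module_labels : array of int, one per taxon
        Planted module membership; taxa in the same module share the
        within-module latent correlation.
    latent_corr : (n_taxa, n_taxa) array
        Latent Gaussian correlation matrix (unit diagonal, positive
        definite after repair).
    base_abundance : array of float
        Per-taxon mean abundance parameters, heavy-tailed across taxa
        (log-normal), as in real amplicon libraries.
    dispersion : float
        Negative-binomial size parameter; smaller = more overdispersed.
    p_loss_drying, evenness_exponent, recovery_mix : float
        Directional drought/rewetting effect parameters (see module
        docstring).
    depth : int
        Reads per sample after multinomial rescaling.
    truth_threshold : float
        |latent correlation| cutoff defining the ground-truth edge set;
        defaults to the screen's rho cutoff (0.7).
    """

    n_taxa: int
    module_labels: np.ndarray
    latent_corr: np.ndarray
    base_abundance: np.ndarray
    dispersion: float
    p_loss_drying: float
    evenness_exponent: float
    recovery_mix: float
    depth: int
    truth_threshold: float = 0.7

    @property
    def taxon_ids(self) -> list[str]:
        width = len(str(self.n_taxa))
        return [f"OTU{str(i + 1).zfill(width)}" for i in range(self.n_taxa)]

    def truth_edges(self, threshold: float | None = None) -> set[tuple[str, str]]:
        """Ground-truth edge set at |latent_corr| >= threshold."""
        thr = self.truth_threshold if threshold is None else threshold
        ids = self.taxon_ids
        edges = set()
        iu, ju = np.triu_indices(self.n_taxa, k=1)
        strong = np.abs(self.latent_corr[iu, ju]) >= thr
        for i, j in zip(iu[strong], ju[strong]):
            edges.add((ids[i], ids[j]))
        return edges

    def to_json(self, path: str | Path) -> None:
        doc = {
            "n_taxa": self.n_taxa,
            "module_labels": self.module_labels.tolist(),
            "base_abundance": self.base_abundance.tolist(),
            "dispersion": self.dispersion,
            "p_loss_drying": self.p_loss_drying,
            "evenness_exponent": self.evenness_exponent,
            "recovery_mix": self.recovery_mix,
            "depth": self.depth,
            "truth_threshold": self.truth_threshold,
            "truth_edges": sorted(self.truth_edges()),
            "latent_corr": np.round(self.latent_corr, 10).tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)


def generate_design(
    n_habitat_levels: int = 3,
    n_hydrology_levels: int = 2,
    reps_per_combo: int = 8,
    blocks: int = 4,
    days: list[int] | tuple[int, ...] = DEFAULT_DAYS,
) -> pd.DataFrame:
    """Fully crossed randomized-block design, one row per (mesocosm, day).

    The default layout — 3 habitat x 2 hydrology treatments, 8 replicates in
    4 spatial blocks (2 replicates per combination per block), 4 sampling
    days — yields 48 mesocosms and 192 sample rows. Deterministic given its
    arguments.
    """
    if n_habitat_levels < 1 or n_hydrology_levels < 1:
        raise ValueError("factor levels must be >= 1")
    if reps_per_combo < 1 or blocks < 1:
        raise ValueError("replicates and blocks must be >= 1")
    if reps_per_combo % blocks != 0:
        raise ValueError(
            f"reps_per_combo ({reps_per_combo}) must be divisible by the "
            f"number of blocks ({blocks}) for a balanced block layout"
        )
    if not days:
        raise ValueError("at least one sampling day is required")
    habitats = [
        _HABITAT_NAMES[i] if i < len(_HABITAT_NAMES) else f"habitat{i + 1}"
        for i in range(n_habitat_levels)
    ]
    hydrologies = [
        _HYDROLOGY_NAMES[i] if i < len(_HYDROLOGY_NAMES) else f"hydrology{i + 1}"
        for i in range(n_hydrology_levels)
    ]
    per_block = reps_per_combo // blocks
    n_meso = n_habitat_levels * n_hydrology_levels * reps_per_combo
    width = max(2, len(str(n_meso)))

    rows = []
    meso = 0
    for block in range(1, blocks + 1):
        for hab in habitats:
            for hyd in hydrologies:
                for _ in range(per_block):
                    meso += 1
                    mid = f"M{str(meso).zfill(width)}"
                    for day in days:
                        rows.append(
                            {
                                "sample_id": f"{mid}_d{day}",
                                "mesocosm_id": mid,
                                "habitat": hab,
                                "hydrology": hyd,
                                "day": int(day),
                                "block": block,
                            }
                        )
    return pd.DataFrame(rows)


def _block_correlation(
    module_labels: np.ndarray, rho_within: float, rho_between: float
) -> np.ndarray:
    same = module_labels[:, None] == module_labels[None, :]
    corr = np.where(same, rho_within, rho_between).astype(float)
    np.fill_diagonal(corr, 1.0)
    return corr


def _nearest_pd(corr: np.ndarray, eig_floor: float = 1e-8) -> np.ndarray:
    """Repair to positive definite by eigenvalue clipping, re-normalised
    to unit diagonal."""
    vals, vecs = np.linalg.eigh(corr)
    if vals.min() >= eig_floor:
        return corr
    vals = np.clip(vals, eig_floor, None)
    fixed = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    vals2 = np.linalg.eigvalsh(fixed)
    if vals2.min() <= 0:
        raise ValueError("correlation matrix could not be repaired to "
                         "positive definite")
    return fixed


def make_truth(
    n_taxa: int = 150,
    n_modules: int = 4,
    rho_within: float = 0.9,
    rho_between: float = 0.0,
    p_loss_drying: float = 0.3,
    evenness_exponent: float = 0.5,
    recovery_mix: float = 0.9,
    depth: int = 10_000,
    seed: int | None = None,
    dispersion: float = 0.5,
    abundance_sigma: float = 1.5,
    truth_threshold: float = 0.7,
) -> TruthSpec:
    """Build a TruthSpec with a block-structured latent correlation matrix.

    Taxa are split into ``n_modules`` near-equal contiguous modules; pairs
    within a module get latent correlation ``rho_within``, pairs across
    modules ``rho_between``. Base mean abundances are log-normal
    (heavy-tailed), scale-free up to the multinomial depth rescaling.
    """
    if n_taxa < 1:
        raise ValueError("n_taxa must be >= 1")
    if n_modules < 1:
        raise ValueError("n_modules must be >= 1")
    if not abs(rho_within) < 1:
        raise ValueError("|rho_within| must be < 1")
    if abs(rho_between) >= abs(rho_within) and not rho_within == rho_between == 0:
        raise ValueError("|rho_between| must be < |rho_within|")
    for name, val in [
        ("p_loss_drying", p_loss_drying),
        ("evenness_exponent", evenness_exponent),
        ("recovery_mix", recovery_mix),
    ]:
        if not 0 <= val <= 1:
            raise ValueError(f"{name} must be in [0, 1], got {val}")
    if evenness_exponent == 0:
        raise ValueError("evenness_exponent must be in (0, 1]")

    rng = np.random.default_rng(seed)
    module_labels = np.sort(np.arange(n_taxa) % n_modules)
    corr = _block_correlation(module_labels, rho_within, rho_between)
    corr = _nearest_pd(corr)
    base = rng.lognormal(mean=0.0, sigma=abundance_sigma, size=n_taxa)
    # scale mean abundances to the library depth: the marginal transform is
    # only rank-preserving when counts are large enough not to tie at zero
    base *= depth / base.sum()
    return TruthSpec(
        n_taxa=n_taxa,
        module_labels=module_labels,
        latent_corr=corr,
        base_abundance=base,
        dispersion=float(dispersion),
        p_loss_drying=float(p_loss_drying),
        evenness_exponent=float(evenness_exponent),
        recovery_mix=float(recovery_mix),
        depth=int(depth),
        truth_threshold=float(truth_threshold),
    )


def _phases(days: np.ndarray) -> dict[int, str]:
    """Map design days to phases: first day = colonization (pre-impact),
    last day = rewetting, interior days = drought. A single-day design is
    all colonization."""
    uniq = sorted(set(int(d) for d in days))
    if len(uniq) == 1:
        return {uniq[0]: "colonization"}
    phases = {uniq[0]: "colonization", uniq[-1]: "rewetting"}
    for d in uniq[1:-1]:
        phases[d] = "drought"
    return phases


def _nb_ppf(u: np.ndarray, mean: np.ndarray, size: float) -> np.ndarray:
    """Negative-binomial quantile transform; zero-mean taxa stay zero."""
    out = np.zeros_like(u, dtype=float)
    pos = mean > 0
    if pos.any():
        p = size / (size + mean[pos])
        out[:, pos] = stats.nbinom.ppf(u[:, pos], size, p)
    return out


def generate_counts(
    truth: TruthSpec,
    design: pd.DataFrame,
    seed: int | None = None,
    persistent_loss: bool = False,
) -> CountTable:
    """Draw a count table for every sample row of ``design``.

    Per sample: latent MVN draw with correlation ``truth.latent_corr`` ->
    uniform scores -> negative-binomial quantiles with condition-adjusted
    means -> multinomial rescale to ``truth.depth`` reads. Drought-phase
    drying samples get taxa zeroed with ``p_loss_drying`` and surviving
    means flattened by ``evenness_exponent``; rewetting-phase drying
    samples are mixed toward control by ``recovery_mix``.

    With ``persistent_loss=True`` the zeroing mask is drawn once per
    mesocosm instead of independently per sample, emulating a taxon that is
    locally extinct for the whole drought.
    """
    required = {"sample_id", "mesocosm_id", "hydrology", "day"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"design table is missing columns: {sorted(missing)}")
    if design.duplicated(["mesocosm_id", "day"]).any():
        raise ValueError("(mesocosm_id, day) pairs must be unique")

    rng = np.random.default_rng(seed)
    n_taxa = truth.n_taxa
    mu0 = truth.base_abundance.astype(float)
    if len(mu0) != n_taxa:
        raise ValueError(
            f"truth declares {n_taxa} taxa but has {len(mu0)} base abundances"
        )
    chol = np.linalg.cholesky(truth.latent_corr)
    phase_of = _phases(design["day"].to_numpy())
    gamma = truth.evenness_exponent
    total0 = mu0.sum()

    def drought_means(mask_keep: np.ndarray) -> np.ndarray:
        mu = np.where(mask_keep, mu0, 0.0) ** gamma
        mu[~mask_keep] = 0.0
        if mu.sum() == 0:
            return mu
        return mu * (total0 / mu.sum())  # keep total mean; depth fixed later anyway

    # Persistent per-mesocosm loss masks, drawn up-front in design order.
    meso_mask: dict[str, np.ndarray] = {}
    if persistent_loss:
        for mid in pd.unique(design["mesocosm_id"]):
            meso_mask[mid] = rng.random(n_taxa) >= truth.p_loss_drying

    counts = np.zeros((len(design), n_taxa), dtype=np.int64)
    for k, row in enumerate(design.itertuples(index=False)):
        z = chol @ rng.standard_normal(n_taxa)
        u = stats.norm.cdf(z)
        u = np.clip(u, 1e-12, 1 - 1e-12)
        phase = phase_of[int(row.day)]
        if row.hydrology == "drying" and phase == "drought":
            keep = (
                meso_mask[row.mesocosm_id]
                if persistent_loss
                else rng.random(n_taxa) >= truth.p_loss_drying
            )
            mu = drought_means(keep)
        elif row.hydrology == "drying" and phase == "rewetting":
            keep = (
                meso_mask[row.mesocosm_id]
                if persistent_loss
                else rng.random(n_taxa) >= truth.p_loss_drying
            )
            mu = truth.recovery_mix * mu0 + (1 - truth.recovery_mix) * drought_means(keep)
        else:
            mu = mu0
        raw = _nb_ppf(u[None, :], mu, truth.dispersion)[0]
        total = raw.sum()
        if total > 0:
            counts[k] = rng.multinomial(truth.depth, raw / total)
    taxa = truth.taxon_ids
    return CountTable(
        pd.DataFrame(counts, index=design["sample_id"].tolist(), columns=taxa)
    )


def evaluate_edge_recovery(
    inferred_edges: set[tuple[str, str]] | list[tuple[str, str]],
    truth: TruthSpec,
    truth_threshold: float | None = None,
) -> dict:
    """Precision/recall of an inferred edge set against the planted truth.

    Edges are unordered taxon pairs. Convention for the degenerate empty
    cases: precision is reported as 1.0 with ``empty_inferred=True`` when
    nothing was inferred (no false positives were made); recall is 1.0 when
    the truth is empty.
    """
    canon = lambda e: tuple(sorted(e))
    inferred = {canon(e) for e in inferred_edges}
    true_set = {canon(e) for e in truth.truth_edges(truth_threshold)}
    known = set(truth.taxon_ids)
    stray = {t for e in inferred for t in e} - known
    if stray:
        raise ValueError(f"inferred edges mention unknown taxa: {sorted(stray)}")
    hits = len(inferred & true_set)
    precision = hits / len(inferred) if inferred else 1.0
    recall = hits / len(true_set) if true_set else 1.0
    return {
        "precision": precision,
        "recall": recall,
        "n_inferred": len(inferred),
        "n_truth": len(true_set),
        "n_hits": hits,
        "empty_inferred": not inferred,
    }


def simulate_experiment(
    seed: int | None = None,
    design_kwargs: dict | None = None,
    truth_kwargs: dict | None = None,
    persistent_loss: bool = False,
) -> tuple[pd.DataFrame, TruthSpec, CountTable]:
    """Convenience wrapper: design + truth + counts in one seeded call."""
    rng = np.random.default_rng(seed)
    design = generate_design(**(design_kwargs or {}))
    truth = make_truth(seed=int(rng.integers(2**31)), **(truth_kwargs or {}))
    table = generate_counts(
        truth, design, seed=int(rng.integers(2**31)), persistent_loss=persistent_loss
    )
    return design, truth, table
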