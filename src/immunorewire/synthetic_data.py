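"""Two-condition scRNA-seq count simulation with planted ground truth, plus
synthetic tumor growth curves.

Counts follow a negative binomial law: gene ``g`` in a cell of type ``t`` has
mean ``mu_high`` when the marker panel marks ``(t, g)`` as expected-high and
``mu_low`` otherwise, scaled by a per-cell lognormal library-size factor and,
in the treated arm, by any configured treatment fold.  One RNG stream is
consumed in a documented order (cell types -> library factors -> counts) so
results are bit-reproducible for a given seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "ScenarioConfig",
    "GrowthScenario",
    "simulate_counts",
    "simulate_growth",
    "default_proportions",
]

CONDITIONS = ("control", "treated")


@dataclass
class CountMatrix:
    """Integer cells x genes counts with identifiers and per-cell metadata."""

    counts: np.ndarray  # (n_cells, n_genes), nonnegative integers
    cell_ids: list[str]
    gene_ids: list[str]
    condition: list[str]  # per cell, in {"control", "treated"}
    true_type: list[str] | None = None  # planted ground truth (synthetic only)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (cells x genes)")
        n_cells, n_genes = self.counts.shape
        if len(self.cell_ids) != n_cells:
            raise ValueError("cell_ids length does not match counts rows")
        if len(self.gene_ids) != n_genes:
            raise ValueError("gene_ids length does not match counts columns")
        if len(set(self.cell_ids)) != n_cells:
            raise ValueError("duplicate cell_ids")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("duplicate gene_ids")
        if len(self.condition) != n_cells:
            raise ValueError("every cell needs a condition label")
        bad = set(self.condition) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")
        if self.true_type is not None and len(self.true_type) != n_cells:
            raise ValueError("true_type length does not match cells")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.floor(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def cell_metadata(self) -> pd.DataFrame:
        meta = pd.DataFrame({"cell_id": self.cell_ids, "condition": self.condition})
        if self.true_type is not None:
            meta["true_type"] = self.true_type
        return meta


def default_proportions() -> dict[str, dict[str, float]]:
    """Myeloid-dominant composition (myeloid sum = 0.60 per condition) with a
    modest treated-arm shift away from Arg1+ M2 toward cytotoxic lymphocytes."""
    control = {
        "M2_noncommitted_NC": 0.08,
        "M2_partial": 0.10,
        "M2": 0.08,
        "Not_committed": 0.05,
        "M1_partial_TAM": 0.06,
        "M1_committed": 0.06,
        "M1_polarized": 0.05,
        "M2_committed_NC": 0.05,
        "Classical_monocyte": 0.04,
        "DC": 0.03,
        "CD8_T": 0.12,
        "CD4_T": 0.12,
        "NK": 0.08,
        "T_M": 0.08,
    }
    treated = dict(control)
    treated["M2_partial"] = 0.06  # fewer Arg1+ M2
    treated["CD8_T"] = 0.14
    treated["NK"] = 0.10
    return {"control": control, "treated": treated}


@dataclass
class ScenarioConfig:
    """Configuration for :func:`simulate_counts`.

    ``cell_type_proportions`` maps condition -> {cell type -> fraction}; each
    condition's fractions must sum to 1.  ``treatment_effects`` lists
    ``(cell_type, gene, fold)`` multiplicative shifts applied to the treated
    arm's NB mean.
    """

    n_cells_per_condition: int = 600
    cell_type_proportions: dict[str, dict[str, float]] = field(
        default_factory=default_proportions
    )
    mu_high: float = 30.0
    mu_low: float = 0.3
    dispersion: float = 4.0
    n_background_genes: int = 30
    treatment_effects: list[tuple[str, str, float]] = field(default_factory=list)
    library_size_cv: float = 0.2
    seed: int = 0

    def validate(self, cell_types: list[str], gene_ids: list[str]) -> None:
        if self.n_cells_per_condition <= 0:
            raise ValueError("n_cells_per_condition must be positive")
        if not (self.mu_high > self.mu_low >= 0):
            raise ValueError("need mu_high > mu_low >= 0")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if self.n_background_genes < 0:
            raise ValueError("n_background_genes must be nonnegative")
        if self.library_size_cv < 0:
            raise ValueError("library_size_cv must be nonnegative")
        for cond in CONDITIONS:
            if cond not in self.cell_type_proportions:
                raise ValueError(f"missing proportions for condition {cond!r}")
            props = self.cell_type_proportions[cond]
            unknown = set(props) - set(cell_types)
            if unknown:
                raise ValueError(
                    f"proportions name unknown cell type(s): {sorted(unknown)}"
                )
            total = sum(props.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"{cond} proportions sum to {total!r}, expected 1"
                )
            if any(p < 0 for p in props.values()):
                raise ValueError("proportions must be nonnegative")
        for ctype, gene, fold in self.treatment_effects:
            if ctype not in cell_types:
                raise ValueError(f"treatment effect names unknown cell type {ctype!r}")
            if gene not in gene_ids:
                raise ValueError(f"treatment effect names unknown gene {gene!r}")
            if fold < 0:
                raise ValueError(f"treatment fold for ({ctype!r}, {gene!r}) is negative")


def _lognormal_params(cv: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with mean 1 and the given CV."""
    if cv == 0:
        return 0.0, 0.0
    sigma2 = math.log(1.0 + cv * cv)
    return -sigma2 / 2.0, math.sqrt(sigma2)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    """NB(mean, dispersion) counts; zero mean is degenerate at 0."""
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if pos.any():
        p = size_param / (size_param + mean[pos])
        out[pos] = rng.negative_binomial(size_param, p)
    return out


def simulate_counts(config: ScenarioConfig, panel=None) -> CountMatrix:
    """Generate a two-condition count matrix with planted cell types.

    Gene set = panel genes (order of first appearance) + ``n_background_genes``
    background genes at ``mu_low``.  The planted type of every cell is recorded
    in ``true_type``.
    """
    if panel is None:
        from .annotate import default_marker_panel

        panel = default_marker_panel()

    cell_types = panel.cell_types
    panel_genes = panel.genes
    bg_genes = [f"Bg{i:04d}" for i in range(config.n_background_genes)]
    gene_ids = panel_genes + bg_genes
    config.validate(cell_types, gene_ids)

    n_genes = len(gene_ids)
    # Base NB mean per (type, gene): mu_high where sign == +1, else mu_low.
    base = np.full((len(cell_types), n_genes), config.mu_low, dtype=float)
    for t_i, ctype in enumerate(cell_types):
        for g_i, gene in enumerate(panel_genes):
            if panel.sign(ctype, gene) == 1:
                base[t_i, g_i] = config.mu_high

    type_means = {"control": base, "treated": base.copy()}
    t_index = {t: i for i, t in enumerate(cell_types)}
    g_index = {g: i for i, g in enumerate(gene_ids)}
    for ctype, gene, fold in config.treatment_effects:
        type_means["treated"][t_index[ctype], g_index[gene]] *= fold

    rng = np.random.default_rng(config.seed)
    n = config.n_cells_per_condition

    # 1) cell types (control block then treated block)
    type_draws: dict[str, np.ndarray] = {}
    for cond in CONDITIONS:
        props = config.cell_type_proportions[cond]
        names = list(props)
        probs = np.array([props[t] for t in names], dtype=float)
        probs = probs / probs.sum()
        type_draws[cond] = rng.choice(len(names), size=n, p=probs)
        type_draws[cond] = np.array([t_index[names[i]] for i in type_draws[cond]])

    # 2) library-size factors for all cells
    mu_ln, sigma_ln = _lognormal_params(config.library_size_cv)
    if sigma_ln > 0:
        lib = rng.lognormal(mean=mu_ln, sigma=sigma_ln, size=2 * n)
    else:
        lib = np.ones(2 * n)

    # 3) counts
    mean_rows = np.empty((2 * n, n_genes), dtype=float)
    true_types: list[str] = []
    condition: list[str] = []
    for b, cond in enumerate(CONDITIONS):
        tm = type_means[cond]
        idx = type_draws[cond]
        mean_rows[b * n : (b + 1) * n] = tm[idx]
        true_types.extend(cell_types[i] for i in idx)
        condition.extend([cond] * n)
    mean_rows *= lib[:, None]
    counts = _nb_draw(rng, mean_rows, config.dispersion)

    cell_ids = [f"{cond[:4]}_{i:05d}" for cond in CONDITIONS for i in range(n)]
    return CountMatrix(
        counts=counts,
        cell_ids=cell_ids,
        gene_ids=gene_ids,
        condition=condition,
        true_type=true_types,
    )


@dataclass
class GrowthScenario:
    """Exponential-growth tumor volume scenario for :func:`simulate_growth`."""

    n_mice_per_group: int = 10
    days: tuple[int, ...] = (0, 3, 5, 7, 10, 12, 14, 17, 19, 21, 24, 26, 28)
    v0_mean: float = 75.0
    growth_rate_control: float = 0.12
    growth_rate_treated: float = 0.12 + math.log(0.34) / 28.0  # 66% endpoint cut
    noise_cv: float = 0.2
    seed: int = 0
    aspect: float = 0.8  # width = aspect * length, aspect <= 1

    def validate(self) -> None:
        if self.n_mice_per_group < 2:
            raise ValueError("need at least 2 mice per group")
        days = list(self.days)
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("days must be strictly increasing")
        if self.v0_mean <= 0:
            raise ValueError("v0_mean must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be nonnegative")
        if not (0 < self.aspect <= 1):
            raise ValueError("aspect must be in (0, 1]")


def simulate_growth(scenario: GrowthScenario):
    """Simulate per-mouse tumor growth: V(day) = v0 * exp(rate * day) * noise.

    Width and length are back-filled from volume with a fixed aspect ratio
    ``k = W/L`` so that (W^2 x L)/2 reproduces V exactly.
    """
    from .growth import GrowthCurveSet

    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    mu_ln, sigma_ln = _lognormal_params(scenario.noise_cv)
    k = scenario.aspect

    rows = []
    rates = {
        "control": scenario.growth_rate_control,
        "treated": scenario.growth_rate_treated,
    }
    days = np.asarray(scenario.days, dtype=float)
    for group in CONDITIONS:
        rate = rates[group]
        for m in range(scenario.n_mice_per_group):
            mouse_id = f"{group[:4]}_m{m:02d}"
            if sigma_ln > 0:
                noise = rng.lognormal(mean=mu_ln, sigma=sigma_ln, size=days.size)
            else:
                noise = np.ones(days.size)
            vol = scenario.v0_mean * np.exp(rate * days) * noise
            # V = (W^2 L)/2 with W = k L  =>  L = (2V / k^2)^(1/3)
            length = np.cbrt(2.0 * vol / (k * k))
            width = k * length
            for d, w, ln_ in zip(scenario.days, width, length):
                rows.append((mouse_id, group, int(d), float(w), float(ln_)))
    frame = pd.DataFrame(
        rows, columns=["mouse_id", "group", "day", "width_mm", "length_mm"]
    )
    return GrowthCurveSet.from_frame(frame)
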