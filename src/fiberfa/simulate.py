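"""Synthetic gastrocnemius-like scRNA-seq data with known fiber-type structure.

The generator emulates probe-based fixed-cell count data from a mixed
muscle sample: four latent cell classes (fast-twitch, slow-twitch, hybrid
fibers expressing both myosin programs, and program-negative non-myofiber
cells), condition labels for a control and two disease severities, a
dedicated mitochondrial gene block so the mito-fraction QC rule is
exercisable, and a configurable depletion of the slow class in diseased
conditions.  Every cell carries ground truth so downstream stages
(QC, factor analysis, classification, profiling) can be validated offline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountMatrix

__all__ = [
    "GenePanel",
    "SimConfig",
    "SyntheticTruth",
    "generate_fiber_counts",
    "generate_go_annotations",
    "default_go_design",
]

FIBER_CLASSES = ("fast", "slow", "hybrid", "negative")


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class GenePanel:
    """Gene universe of the simulator, grouped by biological role.

    ``fast``/``slow`` are the program genes elevated in their class;
    ``neutral`` are myosin relatives expressed in no class (they enter the
    factor panel but should load on neither factor); ``atrophy`` are the
    muscle-atrophy markers carried along for the condition-comparison
    check; ``mito`` genes absorb the per-cell mitochondrial fraction;
    ``filler`` is inert background transcriptome.
    """

    fast: tuple[str, ...] = ("Myh1", "Myh2", "Myh4", "Ckm", "Pygm", "Ttn", "Mybph")
    slow: tuple[str, ...] = ("Myh7", "Myh7b")
    neutral: tuple[str, ...] = ("Myh11", "Myh3")
    atrophy: tuple[str, ...] = ("Fbxo32", "Trim63")
    mito: tuple[str, ...] = (
        "mt-Nd1", "mt-Nd2", "mt-Co1", "mt-Co2",
        "mt-Co3", "mt-Cytb", "mt-Atp6", "mt-Atp8",
    )
    n_filler: int = 40

    @property
    def filler(self) -> tuple[str, ...]:
        return tuple(f"Filler{i:03d}" for i in range(1, self.n_filler + 1))

    @property
    def genes(self) -> tuple[str, ...]:
        return (self.fast + self.slow + self.neutral + self.atrophy
                + self.mito + self.filler)

    def validate(self) -> None:
        genes = self.genes
        if len(genes) == 0:
            raise ConfigurationError("gene panel is empty")
        if len(set(genes)) != len(genes):
            raise ConfigurationError("gene panel contains duplicate ids")


def _default_class_mix() -> dict[str, float]:
    # Gastrocnemius is predominantly fast-twitch; slow fibers are the
    # minority population whose depletion the disease conditions model.
    return {"fast": 0.40, "slow": 0.25, "hybrid": 0.15, "negative": 0.20}


@dataclass
class SimConfig:
    """Study conditions of the simulated experiment.

    Parameters
    ----------
    n_cells_per_condition
        Cells generated per condition label before QC.
    conditions
        Ordered condition labels; the default mirrors a control plus two
        disease severities.
    diseased_conditions
        Conditions whose slow-class probability is multiplied by
        ``slow_depletion``.
    class_mix
        Baseline probability of each latent class.  Either a single
        mapping applied to every condition or a per-condition mapping
        ``{condition: {class: p}}``.
    slow_depletion
        Multiplicative factor in (0, 1] applied to the slow-class
        probability in diseased conditions (remaining mass renormalized).
    program_mean_lfc
        log2 elevation of program genes in cells of their class.
    nb_dispersion
        Negative-binomial dispersion alpha (var = mu + alpha * mu^2).
    mito_frac_mean, mito_frac_sd
        Mean/sd of the per-cell mitochondrial expression fraction.
    libsize_log_mean, libsize_log_sd
        Natural-log mean/sd of the baseline per-cell (non-mito) expected
        total for a program-negative cell; program expression adds on top.
    outlier_frac
        Fraction of cells made to violate QC (half by total >= 5000
        counts, half by mito fraction >= 10%).
    """

    n_cells_per_condition: int = 750
    conditions: tuple[str, ...] = ("Ctrl", "P", "P_PG")
    diseased_conditions: tuple[str, ...] = ("P_PG",)
    gene_panel: GenePanel = field(default_factory=GenePanel)
    class_mix: dict = field(default_factory=_default_class_mix)
    slow_depletion: float = 0.5
    program_mean_lfc: float = 4.0
    nb_dispersion: float = 0.5
    mito_frac_mean: float = 0.03
    mito_frac_sd: float = 0.01
    libsize_log_mean: float = math.log(800.0)
    libsize_log_sd: float = 0.3
    outlier_frac: float = 0.10
    seed: int = 0

    def resolved_mix(self, condition: str) -> dict[str, float]:
        """Class probabilities for one condition, depletion applied."""
        mix = self.class_mix
        if mix and all(isinstance(v, dict) for v in mix.values()):
            if condition not in mix:
                raise ConfigurationError(f"no class_mix for condition {condition!r}")
            probs = dict(mix[condition])
        else:
            probs = dict(mix)
        for cls in FIBER_CLASSES:
            probs.setdefault(cls, 0.0)
        if set(probs) != set(FIBER_CLASSES):
            raise ConfigurationError(
                f"class_mix keys must be {FIBER_CLASSES}, got {sorted(probs)}")
        if any(not (0.0 <= p) or not np.isfinite(p) for p in probs.values()):
            raise ConfigurationError("class probabilities must be finite and >= 0")
        if condition in self.diseased_conditions:
            probs["slow"] *= self.slow_depletion
        total = sum(probs.values())
        if total <= 0:
            raise ConfigurationError("class_mix sums to zero")
        return {k: v / total for k, v in probs.items()}

    def validate(self) -> None:
        if self.n_cells_per_condition < 0:
            raise ConfigurationError("n_cells_per_condition must be >= 0")
        if len(set(self.conditions)) != len(self.conditions):
            raise ConfigurationError("condition labels must be unique")
        if not (0.0 < self.slow_depletion <= 1.0):
            raise ConfigurationError("slow_depletion must be in (0, 1]")
        if not (0.0 <= self.outlier_frac <= 1.0):
            raise ConfigurationError("outlier_frac must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be > 0")
        if self.program_mean_lfc < 0:
            raise ConfigurationError("program_mean_lfc must be >= 0")
        self.gene_panel.validate()
        for cond in self.conditions:
            self.resolved_mix(cond)


@dataclass
class SyntheticTruth:
    """Per-cell ground truth aligned 1:1 with the generated matrix."""

    frame: pd.DataFrame  # cell, condition, true_class, fast_intensity,
    #                      slow_intensity, qc_outlier, outlier_type

    def class_counts(self, condition: str | None = None) -> pd.Series:
        df = self.frame
        if condition is not None:
            df = df[df["condition"] == condition]
        return df["true_class"].value_counts()


def _base_weights(panel: GenePanel) -> pd.Series:
    """Relative expression weight of every non-mito gene in a negative cell."""
    w: dict[str, float] = {}
    for g in panel.fast + panel.slow + panel.neutral:
        w[g] = 0.6
    for g in panel.atrophy:
        w[g] = 1.0
    filler = panel.filler
    if filler:
        for g, b in zip(filler, np.linspace(0.5, 2.0, len(filler))):
            w[g] = b
    return pd.Series(w)


def generate_fiber_counts(config: SimConfig) -> tuple[CountMatrix, SyntheticTruth]:
    """Draw a count matrix plus ground truth from the configured mixture.

    Counts are gamma-Poisson (negative binomial) with class-dependent
    means; the library-size factor multiplies every gene's mean, so the
    log2 fold elevation of program genes is preserved in expectation.
    Deterministic for a fixed config (single counter-based Philox stream).
    """
    config.validate()
    panel = config.gene_panel
    rng = np.random.Generator(np.random.Philox(key=config.seed))

    genes = list(panel.genes)
    non_mito = [g for g in genes if g not in panel.mito]
    base = _base_weights(panel).reindex(non_mito)
    w_neg_total = float(base.sum())

    boost = 2.0 ** config.program_mean_lfc
    n_mito = len(panel.mito)
    nb_n = 1.0 / config.nb_dispersion
    fast_ix = np.array([non_mito.index(g) for g in panel.fast], dtype=int)
    slow_ix = np.array([non_mito.index(g) for g in panel.slow], dtype=int)

    blocks: list[np.ndarray] = []
    frames: list[pd.DataFrame] = []
    for cond in config.conditions:
        mix = config.resolved_mix(cond)
        n = config.n_cells_per_condition
        classes = rng.choice(FIBER_CLASSES, size=n,
                             p=[mix[c] for c in FIBER_CLASSES])
        libsize = np.exp(rng.normal(config.libsize_log_mean,
                                    config.libsize_log_sd, size=n))
        mito_frac = np.clip(rng.normal(config.mito_frac_mean,
                                       config.mito_frac_sd, size=n),
                            1e-3, 0.5)
        is_outlier = rng.random(n) < config.outlier_frac
        # alternate outlier flavors deterministically within the draw order
        out_kind = np.where(np.cumsum(is_outlier) % 2 == 1, "high_count", "high_mito")
        high_count = is_outlier & (out_kind == "high_count")
        high_mito = is_outlier & (out_kind == "high_mito")
        # high-count outliers: expected totals centred well above the
        # 5000-count QC cutoff; high-mito outliers: fraction >= 12%
        libsize[high_count] = np.exp(rng.normal(math.log(9000.0), 0.25,
                                                size=int(high_count.sum())))
        mito_frac[high_mito] = rng.uniform(0.15, 0.35, size=int(high_mito.sum()))

        fast_on = np.isin(classes, ("fast", "hybrid"))
        slow_on = np.isin(classes, ("slow", "hybrid"))
        w = np.tile(base.to_numpy(), (n, 1))
        w[np.ix_(fast_on, fast_ix)] *= boost
        w[np.ix_(slow_on, slow_ix)] *= boost
        # library size scales every mean; class programs add on top
        mu_non_mito = w / w_neg_total * libsize[:, None]
        f = mito_frac[:, None]
        mu_mito = np.repeat(
            f / (1.0 - f) * mu_non_mito.sum(axis=1, keepdims=True) / max(n_mito, 1),
            n_mito, axis=1)
        mu = np.concatenate([mu_non_mito, mu_mito], axis=1)
        blocks.append(rng.negative_binomial(nb_n, nb_n / (nb_n + mu)))
        frames.append(pd.DataFrame({
            "condition": cond,
            "true_class": classes,
            "fast_intensity": np.where(fast_on, boost, 1.0),
            "slow_intensity": np.where(slow_on, boost, 1.0),
            "qc_outlier": is_outlier,
            "outlier_type": np.where(is_outlier, out_kind, "none"),
        }))

    gene_order = non_mito + list(panel.mito)
    if blocks:
        counts = np.vstack(blocks).astype(np.int64)
        truth_body = pd.concat(frames, ignore_index=True)
    else:
        counts = np.zeros((0, len(gene_order)), dtype=np.int64)
        truth_body = pd.DataFrame(columns=[
            "condition", "true_class", "fast_intensity", "slow_intensity",
            "qc_outlier", "outlier_type"])
    n_cells = counts.shape[0]
    cell_ids = [f"cell{i:05d}" for i in range(n_cells)]
    truth = truth_body.copy()
    truth.insert(0, "cell", cell_ids)

    cm = CountMatrix(
        cells=list(cell_ids),
        genes=gene_order,
        counts=counts,
        condition=truth["condition"].tolist(),
    )
    return cm, SyntheticTruth(frame=truth)


# ---------------------------------------------------------------------------
# GO annotation fixtures


def default_go_design() -> dict[str, tuple[int, str | None, float]]:
    """Designed GO-term overlaps: gene -> (n_terms, anchor gene, overlap).

    ``overlap`` is the fraction of the anchor's terms shared.  The design
    makes the myosin relatives Myh7b, Myh11 and Myh3 the three most
    similar non-seed genes (by max Jaccard against the four seed
    markers), with every other gene far behind.
    """
    design: dict[str, tuple[int, str | None, float]] = {
        # seed markers: 10 terms each, fast seeds share a 6-term core
        "Myh1": (10, None, 0.0),
        "Myh2": (10, "Myh1", 0.6),
        "Myh4": (10, "Myh1", 0.6),
        "Myh7": (10, "Myh1", 0.3),
        # similar genes, in intended ranking order
        "Myh7b": (10, "Myh7", 0.6),
        "Myh11": (10, "Myh1", 0.5),
        "Myh3": (10, "Myh2", 0.4),
        # other panel genes share at most one term with any seed
        "Ckm": (8, "Myh1", 0.1),
        "Pygm": (8, None, 0.0),
        "Ttn": (8, "Myh2", 0.1),
        "Mybph": (8, None, 0.0),
        "Fbxo32": (6, None, 0.0),
        "Trim63": (6, None, 0.0),
    }
    return design


def generate_go_annotations(
    design: dict[str, tuple[int, str | None, float]] | None = None,
    extra_genes: list[str] | None = None,
) -> dict[str, set[str]]:
    """Build a gene -> GO-term-set table realizing designed overlaps exactly.

    Each entry ``gene: (n_terms, anchor, overlap)`` gives the gene
    ``round(overlap * len(anchor terms))`` terms copied from its anchor
    (which must appear earlier in the design) plus fresh unique terms up
    to ``n_terms``.  ``extra_genes`` receive disjoint housekeeping terms.
    The construction is deterministic.
    """
    if design is None:
        design = default_go_design()
    table: dict[str, set[str]] = {}
    counter = [0]

    def fresh(k: int) -> list[str]:
        out = [f"GO:{counter[0] + j + 1:07d}" for j in range(k)]
        counter[0] += k
        return out

    for gene, (n_terms, anchor, overlap) in design.items():
        if not (0.0 <= overlap <= 1.0):
            raise ConfigurationError(
                f"overlap fraction for {gene!r} must be in [0, 1], got {overlap}")
        if n_terms < 1:
            raise ConfigurationError(f"{gene!r} needs at least one term")
        shared: list[str] = []
        if anchor is not None:
            if anchor not in table:
                raise ConfigurationError(
                    f"anchor {anchor!r} for {gene!r} not defined earlier")
            pool = sorted(table[anchor])
            k = round(overlap * len(pool))
            if k > n_terms:
                raise ConfigurationError(
                    f"{gene!r}: overlap terms ({k}) exceed n_terms ({n_terms})")
            shared = pool[:k]
        table[gene] = set(shared) | set(fresh(n_terms - len(shared)))
    for gene in extra_genes or []:
        if gene not in table:
            table[gene] = set(fresh(3))
    return table
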