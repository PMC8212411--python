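"""Synthetic scRNA-seq + secretome generator with planted ground truth.

Emulates the study design the pipeline targets: two cohorts of bone-marrow
LSK (Lin- Sca1+ Kit+) progenitors sorted from mice bearing tumors of low or
high metastatic potential, a tumor-secretome densitometry table for the same
two conditions, and a curated ligand->receptor pair table. Ground truth is
planted at three places so every downstream stage is testable:

* a cell-type composition shift between conditions (one progenitor type
  enriched per condition),
* an up-regulation of one receptor gene, confined to one target type in the
  high condition,
* an elevated high/low densitometry ratio for the matching secreted ligand.

Counts follow a negative-binomial (gamma-Poisson) model with a shared
dispersion and a Poisson limit at dispersion 0, the standard noise model for
droplet/plate scRNA-seq counts. Per-cell mitochondrial content is drawn from
a Beta distribution so the mitochondrial QC filter is exercised.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .datatypes import ConfigurationError, CountMatrix, EmptyResultError, ReferenceCompendium

logger = logging.getLogger(__name__)

#: Canonical murine HSPC compartment labels used by the default truth.
DEFAULT_TYPE_NAMES = [
    "LT-HSC", "ST-HSC", "MPP", "MLP", "CLP", "CMP", "GMP", "MDP", "CDP", "MEP",
]

#: Mitochondrially encoded genes present in every simulated gene universe.
MITO_GENES = [
    "mt-Nd1", "mt-Nd2", "mt-Co1", "mt-Co2", "mt-Atp6",
    "mt-Co3", "mt-Nd4", "mt-Nd5", "mt-Cytb", "mt-Rnr1",
]

#: Default cytokine -> receptor-gene pairs (secreted factor label, gene symbol).
DEFAULT_LR_PAIRS = [
    ("IL6", "Il6ra"),
    ("IL6", "Il6st"),
    ("IL2", "Il2rb"),
    ("IL3", "Il3ra"),
    ("IL4", "Il4ra"),
    ("IL10", "Il10ra"),
    ("IL13", "Il13ra1"),
    ("CXCL1", "Cxcr2"),
    ("CXCL10", "Cxcr3"),
    ("CXCL12", "Cxcr4"),
    ("CCL2", "Ccr2"),
    ("CCL5", "Ccr5"),
    ("CSF1", "Csf1r"),
    ("CSF2", "Csf2ra"),
    ("CSF3", "Csf3r"),
    ("IFNG", "Ifngr1"),
    ("TNF", "Tnfrsf1a"),
    ("TGFB1", "Tgfbr1"),
]

#: Secreted factors measured by the default synthetic densitometry panel.
DEFAULT_SECRETOME_FACTORS = sorted({lig for lig, _ in DEFAULT_LR_PAIRS}) + [
    "IL1B", "IL5", "VEGF", "CCL3", "CXCL2",
]

# Fixed sub-stream keys so condition-, secretome- and replicate-level draws are
# independently reproducible from one master seed.
_STREAM_CONDITION_BASE = 0
_STREAM_SECRETOME = 100


@dataclass
class PlantedAxis:
    """The ground-truth cross-talk axis the pipeline should recover."""

    ligand: str = "IL6"
    receptor_gene: str = "Il6ra"
    target_type: str = "MDP"
    receptor_fold: float = 1.21
    ligand_ratio: float = 2.5


@dataclass
class SimulationTruth:
    """Full parameterisation of one synthetic experiment.

    The defaults encode the statistical structure of the study the pipeline
    was built for: ~10 progenitor types with disjoint marker programs, the
    MDP compartment enriched from 10% to 25% of cells in the high-metastatic
    condition, a 1.21-fold Il6ra up-regulation confined to high-condition
    MDPs, and an IL-6 densitometry ratio of 2.5 between conditions.
    """

    n_types: int = 10
    type_names: list[str] = field(default_factory=lambda: list(DEFAULT_TYPE_NAMES))
    n_genes: int = 2000
    markers_per_type: int = 30
    baseline_mean: float = 1.0
    marker_fold: float = 8.0
    proportions_by_condition: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "low": _spread_proportions({"MDP": 0.10, "GMP": 0.20}),
            "high": _spread_proportions({"MDP": 0.25, "GMP": 0.10}),
        }
    )
    planted_axis: PlantedAxis = field(default_factory=PlantedAxis)
    n_cells_per_condition: dict[str, int] = field(
        default_factory=lambda: {"low": 400, "high": 400}
    )
    library_size_mean: float = 5000.0
    library_size_sigma: float = 0.3
    dropout_dispersion: float = 0.3
    mito_fraction_mean: float = 0.02
    mito_fraction_concentration: float = 60.0
    receptor_genes: list[str] = field(
        default_factory=lambda: [rec for _, rec in DEFAULT_LR_PAIRS]
    )
    receptor_expression_fold: float = 10.0
    secretome_factors: list[str] = field(
        default_factory=lambda: list(DEFAULT_SECRETOME_FACTORS)
    )
    secretome_noise_sd: float = 0.1
    secretome_base_level: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if self.n_types != len(self.type_names):
            raise ConfigurationError(
                f"n_types={self.n_types} but {len(self.type_names)} type names"
            )
        if len(set(self.type_names)) != self.n_types:
            raise ConfigurationError("type names must be unique")
        n_special = len(self.special_genes())
        if self.n_types * self.markers_per_type + n_special > self.n_genes:
            raise ConfigurationError(
                "marker assignment exceeds gene universe: "
                f"{self.n_types} x {self.markers_per_type} markers + "
                f"{n_special} named genes > {self.n_genes} genes"
            )
        for cond, props in self.proportions_by_condition.items():
            if set(props) != set(self.type_names):
                raise ConfigurationError(
                    f"proportions for condition {cond!r} must cover every type"
                )
            total = sum(props.values())
            if abs(total - 1.0) > 1e-12:
                raise ConfigurationError(
                    f"proportions for condition {cond!r} sum to {total}, not 1"
                )
            if any(p < 0 for p in props.values()):
                raise ConfigurationError("proportions must be >= 0")
        ax = self.planted_axis
        if ax.receptor_fold < 1 or ax.ligand_ratio < 1:
            raise ConfigurationError("receptor_fold and ligand_ratio must be >= 1")
        if ax.receptor_gene not in self.receptor_genes:
            raise ConfigurationError(
                f"planted receptor {ax.receptor_gene!r} missing from receptor gene list"
            )
        if ax.ligand not in self.secretome_factors:
            raise ConfigurationError(
                f"planted ligand {ax.ligand!r} missing from secretome factor list"
            )
        if ax.target_type not in self.type_names:
            raise ConfigurationError(
                f"planted target type {ax.target_type!r} is not a simulated type"
            )
        if set(self.n_cells_per_condition) != set(self.proportions_by_condition):
            raise ConfigurationError(
                "n_cells_per_condition and proportions_by_condition must share conditions"
            )
        for name, value in [
            ("baseline_mean", self.baseline_mean),
            ("dropout_dispersion", self.dropout_dispersion),
            ("library_size_mean", self.library_size_mean),
        ]:
            if value < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.marker_fold < 1:
            raise ConfigurationError("marker_fold must be >= 1")
        if not 0 <= self.mito_fraction_mean < 1:
            raise ConfigurationError("mito_fraction_mean must be in [0, 1)")

    # -- gene universe ------------------------------------------------------

    def special_genes(self) -> list[str]:
        """Named genes (receptors + mitochondrial) reserved in the universe."""
        named: dict[str, None] = {}
        for g in self.receptor_genes:
            named.setdefault(g, None)
        for g in MITO_GENES:
            named.setdefault(g, None)
        return list(named)

    def gene_ids(self) -> list[str]:
        special = self.special_genes()
        n_fill = self.n_genes - len(special)
        fillers = [f"g{i:04d}" for i in range(n_fill)]
        return special + fillers

    def marker_genes(self) -> dict[str, list[str]]:
        """Marker ledger: disjoint marker gene sets per type (filler genes only)."""
        special = self.special_genes()
        genes = self.gene_ids()
        pool = genes[len(special):]
        out: dict[str, list[str]] = {}
        for i, t in enumerate(self.type_names):
            out[t] = pool[i * self.markers_per_type:(i + 1) * self.markers_per_type]
        return out

    def mito_genes(self) -> list[str]:
        return list(MITO_GENES)

    # -- expected expression ------------------------------------------------

    def rate_matrix(self) -> tuple[np.ndarray, list[str]]:
        """Relative expected expression rates, (n_types, n_genes).

        Mitochondrial genes carry rate 0 here; their per-cell share is drawn
        separately in :func:`simulate_counts` from the Beta model.
        """
        genes = self.gene_ids()
        gene_pos = {g: i for i, g in enumerate(genes)}
        rates = np.full((self.n_types, self.n_genes), self.baseline_mean)
        for g in self.receptor_genes:
            rates[:, gene_pos[g]] = self.baseline_mean * self.receptor_expression_fold
        for t, markers in self.marker_genes().items():
            ti = self.type_names.index(t)
            for g in markers:
                rates[ti, gene_pos[g]] = self.baseline_mean * self.marker_fold
        for g in MITO_GENES:
            rates[:, gene_pos[g]] = 0.0
        return rates, genes

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationTruth":
        d = dict(d)
        if isinstance(d.get("planted_axis"), dict):
            d["planted_axis"] = PlantedAxis(**d["planted_axis"])
        return cls(**d)


def _spread_proportions(fixed: dict[str, float]) -> dict[str, float]:
    """Fill non-fixed default types with equal shares of the remaining mass."""
    rest = [t for t in DEFAULT_TYPE_NAMES if t not in fixed]
    remaining = 1.0 - sum(fixed.values())
    share = remaining / len(rest)
    props = {t: fixed.get(t, share) for t in DEFAULT_TYPE_NAMES}
    # exact unit mass despite float division
    residual = 1.0 - sum(props.values())
    props[rest[-1]] += residual
    return props


def _stream(seed: int, key: int) -> np.random.Generator:
    """Sub-stream derived from the master seed by a fixed offset key."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


# ---------------------------------------------------------------------------
# reference compendium
# ---------------------------------------------------------------------------

def generate_reference(truth: SimulationTruth) -> ReferenceCompendium:
    """Noise-free per-type profiles on the annotation (log CP10K) scale.

    Mitochondrial genes are excluded from the compendium: sorted-population
    reference transcriptomes are used for identity, not QC, and per-cell
    mitochondrial load is a technical covariate the annotation should ignore.
    """
    truth.validate()
    rates, genes = truth.rate_matrix()
    keep = [i for i, g in enumerate(genes) if g not in set(MITO_GENES)]
    rates = rates[:, keep]
    genes = [genes[i] for i in keep]
    cp10k = rates / rates.sum(axis=1, keepdims=True) * 1e4
    return ReferenceCompendium(
        profiles=np.log1p(cp10k),
        type_names=list(truth.type_names),
        gene_ids=genes,
    )


# ---------------------------------------------------------------------------
# count matrix
# ---------------------------------------------------------------------------

def simulate_counts(truth: SimulationTruth) -> CountMatrix:
    """Draw a gene x cell count matrix; a pure function of ``truth``.

    Per condition: cell types are drawn from the planted composition,
    library sizes from a log-normal around ``library_size_mean``, the
    mitochondrial fraction from a Beta around ``mito_fraction_mean``, and
    counts from a gamma-Poisson mixture (negative binomial with dispersion
    ``dropout_dispersion``; exact Poisson at dispersion 0). Cells of the
    planted target type in the ``high`` condition get the planted receptor
    gene's rate multiplied by ``receptor_fold``.
    """
    truth.validate()
    total_cells = sum(truth.n_cells_per_condition.values())
    if total_cells <= 0:
        raise EmptyResultError("zero cells requested")

    rates, genes = truth.rate_matrix()
    gene_pos = {g: i for i, g in enumerate(genes)}
    receptor_idx = gene_pos[truth.planted_axis.receptor_gene]
    target_idx = truth.type_names.index(truth.planted_axis.target_type)
    mito_idx = np.array([gene_pos[g] for g in MITO_GENES])
    nonmito = rates.copy()

    blocks: list[np.ndarray] = []
    cell_ids: list[str] = []
    conditions: list[str] = []
    true_types: list[str] = []

    for ci, cond in enumerate(truth.proportions_by_condition):
        n_cells = truth.n_cells_per_condition[cond]
        if n_cells == 0:
            continue
        rng = _stream(truth.seed, _STREAM_CONDITION_BASE + ci)
        props = np.array(
            [truth.proportions_by_condition[cond][t] for t in truth.type_names]
        )
        type_idx = rng.choice(truth.n_types, size=n_cells, p=props)
        mu_log = np.log(truth.library_size_mean) - truth.library_size_sigma**2 / 2
        libs = rng.lognormal(mean=mu_log, sigma=truth.library_size_sigma, size=n_cells)
        if truth.mito_fraction_mean > 0:
            conc = truth.mito_fraction_concentration
            a = truth.mito_fraction_mean * conc
            b = (1 - truth.mito_fraction_mean) * conc
            mito_f = rng.beta(a, b, size=n_cells)
        else:
            mito_f = np.zeros(n_cells)

        cell_rates = nonmito[type_idx]  # (cells, genes); fancy indexing copies
        if cond == "high":
            on_target = type_idx == target_idx
            cell_rates[on_target, receptor_idx] *= truth.planted_axis.receptor_fold
        row_sums = cell_rates.sum(axis=1, keepdims=True)
        mu = cell_rates / row_sums * (libs * (1 - mito_f))[:, None]
        mu[:, mito_idx] = (libs * mito_f / len(mito_idx))[:, None]

        if truth.dropout_dispersion == 0:
            counts = rng.poisson(mu)
        else:
            shape = 1.0 / truth.dropout_dispersion
            lam = rng.gamma(shape, scale=truth.dropout_dispersion * mu)
            counts = rng.poisson(lam)
        blocks.append(counts)
        cell_ids.extend(f"{cond}_{i:05d}" for i in range(n_cells))
        conditions.extend([cond] * n_cells)
        true_types.extend(truth.type_names[t] for t in type_idx)

    counts = np.vstack(blocks).T.astype(np.int64)  # genes x cells
    return CountMatrix(
        counts=counts,
        gene_ids=genes,
        cell_ids=cell_ids,
        condition=np.array(conditions, dtype=object),
        true_type=np.array(true_types, dtype=object),
    )


# ---------------------------------------------------------------------------
# secretome + ligand-receptor tables
# ---------------------------------------------------------------------------

def simulate_secretome(truth: SimulationTruth) -> pd.DataFrame:
    """Two-condition densitometry table with the planted ligand elevated.

    Returns a DataFrame with columns ``factor``, ``dens_low``, ``dens_high``,
    ``ratio``. The planted ligand's high/low ratio is centered on
    ``ligand_ratio``; every other factor's ratio is centered on 1. Noise is
    multiplicative log-normal with sd ``secretome_noise_sd`` (0 = exact).
    """
    truth.validate()
    rng = _stream(truth.seed, _STREAM_SECRETOME)
    factors = list(truth.secretome_factors)
    base = truth.secretome_base_level
    sd = truth.secretome_noise_sd
    n = len(factors)
    noise_low = np.exp(rng.normal(0.0, sd, size=n)) if sd > 0 else np.ones(n)
    noise_high = np.exp(rng.normal(0.0, sd, size=n)) if sd > 0 else np.ones(n)
    ratio_param = np.array(
        [truth.planted_axis.ligand_ratio if f == truth.planted_axis.ligand else 1.0
         for f in factors]
    )
    dens_low = base * noise_low
    dens_high = base * ratio_param * noise_high
    return pd.DataFrame(
        {
            "factor": factors,
            "dens_low": dens_low,
            "dens_high": dens_high,
            "ratio": dens_high / dens_low,
        }
    )


def make_lr_table(pairs: list[tuple[str, str]] | None = None) -> pd.DataFrame:
    """Deduplicated ligand -> receptor-gene pair table.

    One ligand may map to several receptors and vice versa. With ``None``
    the default curated cytokine/receptor panel is returned.
    """
    if pairs is None:
        pairs = DEFAULT_LR_PAIRS
    if len(pairs) == 0:
        warnings.warn("empty ligand-receptor pair list; returning empty table")
        return pd.DataFrame(columns=["ligand", "receptor"])
    seen: dict[tuple[str, str], None] = {}
    for lig, rec in pairs:
        if not lig or not rec:
            raise ConfigurationError("ligand and receptor labels must be non-empty")
        seen.setdefault((str(lig), str(rec)), None)
    ligs, recs = zip(*seen.keys())
    return pd.DataFrame({"ligand": list(ligs), "receptor": list(recs)})
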