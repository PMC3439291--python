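"""Synthetic expression, annotation, and clinical cohorts for pipeline testing.

The generators emulate a two-group tumor-recurrence study design: patients who
relapse within 12 months of surgery ("recurrence") versus patients relapse-free
for at least 36 months ("non-recurrence"), optionally with a healthy control
group.  Expression is Gaussian on the log scale; a configurable number of genes
is mean-shifted between the patient groups, and planted gene modules are given
group-specific within-module correlation through a single latent factor per
module, so that both differential expression and differential *co-expression*
are present and recoverable.  Survival times follow an exponential
proportional-hazards model driven by planted marker genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

RECURRENCE = "recurrence"
NON_RECURRENCE = "non-recurrence"
HEALTHY = "healthy"
EXCLUDED = "excluded"

#: recurrence-group rule: event within this many months
RECURRENCE_CUTOFF_MONTHS = 12.0
#: non-recurrence-group rule: relapse-free for at least this many months
NON_RECURRENCE_CUTOFF_MONTHS = 36.0


@dataclass(frozen=True)
class ModuleSpec:
    """A planted co-expression module.

    ``size`` genes share a latent factor; the first ``n_hubs`` of them load on
    it more strongly, so they correlate with every module member at least as
    tightly as ordinary members correlate with each other.  ``r_group1`` /
    ``r_group2`` are the target member-member Pearson correlations in the
    recurrence and non-recurrence groups respectively.  ``de_direction``
    ("up", "down", or None) additionally mean-shifts the module's genes in the
    recurrence group, making them differentially expressed as well as
    differentially co-expressed — the profile of a credible recurrence marker.
    """

    size: int
    n_hubs: int
    r_group1: float
    r_group2: float
    de_direction: str | None = None

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError("module size must be >= 2")
        if not 0 <= self.n_hubs <= self.size:
            raise ValueError("hub count must be between 0 and module size")
        for r in (self.r_group1, self.r_group2):
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"module correlation {r} outside [-1, 1]")
        if self.de_direction not in (None, "up", "down"):
            raise ValueError("de_direction must be 'up', 'down', or None")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the synthetic cohort.

    Defaults mirror the validation cohort the pipeline targets: 35 recurrence
    and 45 non-recurrence patients, a 2000-gene panel with a couple of hundred
    truly differential genes (shifted by ``de_effect`` noise SDs in the
    recurrence group), and one differentially co-expressed module per
    direction.  Hazards are in events per month.
    """

    n_genes: int = 2000
    n_recurrence: int = 35
    n_nonrecurrence: int = 45
    n_healthy: int = 0
    n_de_up: int = 100
    n_de_down: int = 100
    de_effect: float = 2.0
    module_specs: tuple[ModuleSpec, ...] = (
        ModuleSpec(size=20, n_hubs=5, r_group1=0.9, r_group2=0.0, de_direction="up"),
        ModuleSpec(size=20, n_hubs=5, r_group1=0.0, r_group2=0.9, de_direction="down"),
    )
    noise_sd: float = 1.0
    baseline_hazard: float = 0.02
    log_hr_per_marker: float = float(np.log(2.0))
    censor_time_max: float = 60.0
    seed: int = 0
    marker_genes: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "module_specs", tuple(self.module_specs))
        if self.marker_genes is not None:
            object.__setattr__(self, "marker_genes", tuple(self.marker_genes))
        counts = {
            "n_genes": self.n_genes,
            "n_recurrence": self.n_recurrence,
            "n_nonrecurrence": self.n_nonrecurrence,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be > 0, got {value}")
        if self.n_healthy < 0:
            raise ValueError("n_healthy must be >= 0")
        if self.n_de_up < 0 or self.n_de_down < 0:
            raise ValueError("DE gene counts must be >= 0")
        if self.n_de_up + self.n_de_down > self.n_genes:
            raise ValueError("n_de_up + n_de_down exceeds n_genes")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.censor_time_max <= NON_RECURRENCE_CUTOFF_MONTHS:
            raise ValueError(
                "censor_time_max must exceed the non-recurrence cutoff "
                f"({NON_RECURRENCE_CUTOFF_MONTHS} months)"
            )
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        n_module = sum(m.size for m in self.module_specs)
        if self.n_de_up + self.n_de_down + n_module > self.n_genes:
            raise ValueError(
                "DE genes plus module genes exceed n_genes; modules are kept "
                "disjoint from DE genes and from each other"
            )


@dataclass
class PlantedTruth:
    """Record of the structure planted by the generator."""

    de_up: frozenset[str]
    de_down: frozenset[str]
    module_genes: tuple[frozenset[str], ...]
    hub_genes: tuple[frozenset[str], ...]

    @property
    def de_genes(self) -> frozenset[str]:
        return self.de_up | self.de_down

    @property
    def all_hubs(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for hubs in self.hub_genes:
            out |= hubs
        return out


@dataclass
class LabeledExpressionMatrix:
    """Genes x samples log-expression with per-sample group labels.

    ``values`` is a DataFrame indexed by gene ID with sample-ID columns;
    ``group`` maps every sample to recurrence / non-recurrence / healthy.
    """

    values: pd.DataFrame
    group: pd.Series
    truth: PlantedTruth | None = None

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.group.index):
            raise ValueError("group labels must be indexed by the sample IDs")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, label: str) -> list[str]:
        return list(self.group.index[self.group == label])

    def subset_genes(self, genes: Sequence[str]) -> "LabeledExpressionMatrix":
        missing = set(genes) - set(self.values.index)
        if missing:
            raise KeyError(f"genes absent from matrix: {sorted(missing)[:5]}")
        return LabeledExpressionMatrix(
            values=self.values.loc[list(genes)], group=self.group, truth=self.truth
        )


@dataclass
class ClinicalTable:
    """Per-patient covariates, marker expression, and recurrence-free survival.

    ``data`` has one row per patient: ``time_months``, ``event`` (1 = relapse
    observed), ``group`` (rule-derived label), categorical covariates, and one
    ``marker_<gene>`` column per planted marker gene.  ``n_discarded`` counts
    samples dropped because no drawn survival time was consistent with their
    pre-assigned expression group.
    """

    data: pd.DataFrame
    marker_genes: tuple[str, ...]
    n_discarded: int = 0

    def __post_init__(self) -> None:
        required = {"time_months", "event", "group"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"clinical table missing columns: {sorted(missing)}")
        if (self.data["time_months"] <= 0).any():
            raise ValueError("time_months must be > 0")
        if not self.data["event"].isin([0, 1]).all():
            raise ValueError("event must be 0/1")
        rec = self.data[self.data["group"] == RECURRENCE]
        if len(rec) and not (
            (rec["event"] == 1).all()
            & (rec["time_months"] <= RECURRENCE_CUTOFF_MONTHS).all()
        ):
            raise ValueError("recurrence-group rows must have event=1 and time <= 12")
        non = self.data[self.data["group"] == NON_RECURRENCE]
        if len(non) and not (
            (non["event"] == 0).all()
            & (non["time_months"] >= NON_RECURRENCE_CUTOFF_MONTHS).all()
        ):
            raise ValueError("non-recurrence-group rows must have event=0 and time >= 36")


@dataclass
class AnnotationCollection:
    """Gene-set annotations: term id -> (name, member genes), plus a universe."""

    terms: dict[str, tuple[str, frozenset[str]]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for term_id, (_, members) in self.terms.items():
            if not members:
                raise ValueError(f"term {term_id} is empty")
            stray = members - self.universe
            if stray:
                raise ValueError(
                    f"term {term_id} has members outside the universe: "
                    f"{sorted(stray)[:5]}"
                )

    def __len__(self) -> int:
        return len(self.terms)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationCollection):
            return NotImplemented
        return self.terms == other.terms and self.universe == other.universe


class SimulationError(RuntimeError):
    """The simulated cohort is degenerate under the requested configuration."""


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{str(i).zfill(width)}" for i in range(n)]


def generate_expression(config: SimulationConfig) -> LabeledExpressionMatrix:
    """Draw a labelled log-expression matrix with planted DE genes and modules.

    Layout of the gene index: DE-up genes first, then DE-down, then module
    genes (modules consecutive, hubs first within each module), then pure
    noise genes.  DE genes are shifted by ``+/- de_effect * noise_sd`` in the
    recurrence group only, so the non-recurrence and healthy groups share one
    baseline distribution.  Each module draws its members as
    ``lam * f_g + sqrt(1 - lam^2) * eps`` with a per-group latent factor
    ``f_g``, giving member-member correlation ``lam_m^2 = r_group`` and
    hub-member correlation ``lam_h * lam_m >= r_group``.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    groups = (
        [RECURRENCE] * config.n_recurrence
        + [NON_RECURRENCE] * config.n_nonrecurrence
        + [HEALTHY] * config.n_healthy
    )
    n_samples = len(groups)
    samples = [f"S{str(i).zfill(3)}" for i in range(n_samples)]
    group = pd.Series(groups, index=samples, name="group")

    x = rng.normal(0.0, config.noise_sd, size=(config.n_genes, n_samples))

    is_rec = np.asarray([g == RECURRENCE for g in groups])
    shift = config.de_effect * config.noise_sd
    up = slice(0, config.n_de_up)
    down = slice(config.n_de_up, config.n_de_up + config.n_de_down)
    x[up, is_rec] += shift
    x[down, is_rec] -= shift

    module_genes: list[frozenset[str]] = []
    hub_genes: list[frozenset[str]] = []
    pos = config.n_de_up + config.n_de_down
    group_masks = {
        RECURRENCE: is_rec,
        NON_RECURRENCE: np.asarray([g == NON_RECURRENCE for g in groups]),
        HEALTHY: np.asarray([g == HEALTHY for g in groups]),
    }
    for mod in config.module_specs:
        rows = np.arange(pos, pos + mod.size)
        pos += mod.size
        targets = {
            RECURRENCE: mod.r_group1,
            NON_RECURRENCE: mod.r_group2,
            HEALTHY: mod.r_group2,  # controls share the non-recurrence structure
        }
        for label, mask in group_masks.items():
            n_g = int(mask.sum())
            if n_g == 0:
                continue
            r = targets[label]
            lam_member = np.sign(r) * np.sqrt(abs(r))
            # hubs load as |r|**0.25 so hub-member correlation |r|**0.75 >= |r|
            lam_hub = np.sign(r) * abs(r) ** 0.25 if r != 0 else 0.0
            lam = np.full(mod.size, lam_member)
            lam[: mod.n_hubs] = lam_hub
            factor = rng.normal(0.0, 1.0, size=n_g)
            eps = rng.normal(0.0, 1.0, size=(mod.size, n_g))
            block = lam[:, None] * factor[None, :]
            block += np.sqrt(1.0 - lam[:, None] ** 2) * eps
            x[np.ix_(rows, mask)] = config.noise_sd * block
        if mod.de_direction == "up":
            x[np.ix_(rows, is_rec)] += shift
        elif mod.de_direction == "down":
            x[np.ix_(rows, is_rec)] -= shift
        ids = [genes[i] for i in rows]
        module_genes.append(frozenset(ids))
        hub_genes.append(frozenset(ids[: mod.n_hubs]))

    extra_up = frozenset().union(
        *[
            m
            for m, spec in zip(module_genes, config.module_specs)
            if spec.de_direction == "up"
        ],
        frozenset(),
    )
    extra_down = frozenset().union(
        *[
            m
            for m, spec in zip(module_genes, config.module_specs)
            if spec.de_direction == "down"
        ],
        frozenset(),
    )
    truth = PlantedTruth(
        de_up=frozenset(genes[up]) | extra_up,
        de_down=frozenset(genes[down]) | extra_down,
        module_genes=tuple(module_genes),
        hub_genes=tuple(hub_genes),
    )
    values = pd.DataFrame(x, index=genes, columns=samples)
    return LabeledExpressionMatrix(values=values, group=group, truth=truth)


def default_marker_genes(
    expr: LabeledExpressionMatrix, config: SimulationConfig
) -> tuple[str, ...]:
    """Markers driving the hazard: config override, else hubs of module 1,
    else the first DE-up genes."""
    if config.marker_genes is not None:
        return tuple(config.marker_genes)
    if expr.truth is not None and expr.truth.hub_genes and expr.truth.hub_genes[0]:
        return tuple(sorted(expr.truth.hub_genes[0]))
    return tuple(expr.gene_ids[: min(3, len(expr.gene_ids))])


def _marker_score(expr: LabeledExpressionMatrix, markers: Sequence[str]) -> pd.Series:
    sub = expr.values.loc[list(markers)]
    score = sub.mean(axis=0)
    return (score - score.mean()) / max(score.std(ddof=0), 1e-12)


def _draw_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Clinicopathologic covariates with marginals loosely matching an early-
    stage HBV-related HCC cohort (binary AFP class, tumor number, cirrhosis,
    differentiation grade; age in years; sex)."""
    return pd.DataFrame(
        {
            "afp_high": rng.binomial(1, 0.45, n),
            "tumor_multiple": rng.binomial(1, 0.4, n),
            "cirrhosis": rng.binomial(1, 0.65, n),
            "grade_high": rng.binomial(1, 0.45, n),
            "age": rng.integers(30, 71, n),
            "sex_male": rng.binomial(1, 0.87, n),
        }
    )


def _classify(time: float, event: int) -> str:
    if event == 1 and time <= RECURRENCE_CUTOFF_MONTHS:
        return RECURRENCE
    if event == 0 and time >= NON_RECURRENCE_CUTOFF_MONTHS:
        return NON_RECURRENCE
    return EXCLUDED


def generate_clinical(
    expr: LabeledExpressionMatrix,
    config: SimulationConfig,
    *,
    match_expression_groups: bool = True,
    max_redraws: int = 1000,
) -> ClinicalTable:
    """Simulate recurrence-free survival tied to planted marker expression.

    Event times are exponential with rate
    ``baseline_hazard * exp(log_hr_per_marker * marker_score)`` where the
    marker score is the standardized mean expression of the marker genes.
    Follow-up ends administratively at a per-patient time drawn uniformly on
    [36, censor_time_max] months (staggered study entry).  Patients are
    labelled by the two-group rule: relapse within 12 months -> recurrence;
    relapse-free at 36 months -> non-recurrence; anything between is
    inconsistent with the design.

    With ``match_expression_groups=True`` (the pipeline default) times are
    redrawn until the rule label agrees with the patient's expression-group
    label; patients failing after ``max_redraws`` attempts are discarded and
    counted.  With ``False`` each patient is drawn once and keeps the rule
    label (between-cutoff rows labelled ``excluded``) — the unconditional
    cohort appropriate for hazard-model parameter-recovery studies.
    """
    rng = np.random.default_rng(np.random.default_rng(config.seed).integers(2**31) + 1)
    markers = default_marker_genes(expr, config)
    missing = set(markers) - set(expr.gene_ids)
    if missing:
        raise KeyError(f"marker genes absent from expression: {sorted(missing)}")
    tumor_samples = [s for s in expr.sample_ids if expr.group[s] != HEALTHY]
    score = _marker_score(expr, markers)
    rates = config.baseline_hazard * np.exp(
        config.log_hr_per_marker * score[tumor_samples].to_numpy()
    )

    rows = []
    n_discarded = 0
    for sample, rate in zip(tumor_samples, rates):
        want = expr.group[sample] if match_expression_groups else None
        for _ in range(max_redraws if match_expression_groups else 1):
            t_event = rng.exponential(1.0 / rate)
            c = rng.uniform(NON_RECURRENCE_CUTOFF_MONTHS, config.censor_time_max)
            time = min(t_event, c)
            event = int(t_event <= c)
            label = _classify(time, event)
            if want is None or label == want:
                break
        else:
            n_discarded += 1
            continue
        rows.append((sample, time, event, label))

    if not rows:
        raise SimulationError(
            "every simulated patient was discarded; the hazard configuration "
            "is inconsistent with the two-group design — lower baseline_hazard "
            "or log_hr_per_marker, or raise censor_time_max"
        )

    data = pd.DataFrame(
        rows, columns=["patient_id", "time_months", "event", "group"]
    ).set_index("patient_id")
    cov = _draw_covariates(rng, len(data))
    cov.index = data.index
    data = pd.concat([data, cov], axis=1)
    for g in markers:
        data[f"marker_{g}"] = expr.values.loc[g, data.index].to_numpy()
    return ClinicalTable(data=data, marker_genes=markers, n_discarded=n_discarded)


def generate_annotations(
    config: SimulationConfig,
    expr: LabeledExpressionMatrix,
    *,
    n_random_terms: int = 30,
    size_range: tuple[int, int] = (10, 200),
) -> AnnotationCollection:
    """Emit gene-set annotations over the expression universe.

    Includes one positive-control term equal to the planted DE gene set (so a
    downstream enrichment scan has a known winner), one size-matched random
    term per direction as a negative control, and ``n_random_terms`` random
    terms with sizes log-uniform in ``size_range``.
    """
    rng = np.random.default_rng(np.random.default_rng(config.seed).integers(2**31) + 2)
    universe = frozenset(expr.gene_ids)
    genes = np.asarray(expr.gene_ids)
    terms: dict[str, tuple[str, frozenset[str]]] = {}

    if expr.truth is not None and expr.truth.de_genes:
        de = expr.truth.de_genes
        terms["TERM_POS"] = ("planted positive control", frozenset(de))
        matched = rng.choice(genes, size=len(de), replace=False)
        terms["TERM_NEG_MATCHED"] = (
            "size-matched random control",
            frozenset(matched.tolist()),
        )
    lo, hi = size_range
    hi = min(hi, len(genes))
    for i in range(n_random_terms):
        size = int(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        members = rng.choice(genes, size=max(size, 1), replace=False)
        terms[f"TERM_R{i:03d}"] = (f"random term {i}", frozenset(members.tolist()))
    return AnnotationCollection(terms=terms, universe=universe)
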