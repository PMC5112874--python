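"""Synthetic two-subtype cohorts for exercising the full analysis chain.

The generator emulates an FFPE bladder-cancer series profiled on a
targeted panel: two transcriptional groups (basal-like / luminal-like)
over ~90 target genes plus housekeeping genes, a subset of genes truly
differentially expressed with a fixed log2 effect, independent Gaussian
noise on the log2 scale, FGFR3 mutations drawn with group-specific
frequency (high in luminal, low in basal), and a clinical-stage mix
(NMIBC / MIBC / MET) that skews NMIBC-luminal and MET-basal.

Cohorts can be re-encoded as triplicate qPCR Ct tables with per-assay
reaction-failure probabilities, mimicking degraded FFPE template.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import BASAL, CtTable, ExpressionMatrix, LUMINAL, PanelDefinition

STAGES = ("NMIBC", "MIBC", "MET")

#: marker gene carrying the largest luminal-directed effect
MARKER_GENE = "FGFR3"

# Stage composition per subtype.  A balanced basal/luminal cohort mixes to
# ~45.5/30/26% NMIBC/MIBC/MET overall, with NMIBC enriched in the luminal
# group and MET in the basal group.
DEFAULT_STAGE_MIX = {
    LUMINAL: (0.71, 0.24, 0.05),
    BASAL: (0.20, 0.33, 0.47),
}


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic basal/luminal cohort.

    ``effect`` is the full between-group mean shift (log2 units) applied to
    each differentially expressed gene; ``noise_sd`` the per-gene Gaussian
    noise SD on the log2 scale.  Mutation frequencies are per-group
    Bernoulli probabilities for the marker gene.
    """

    n_basal: int = 102
    n_luminal: int = 102
    n_genes: int = 90
    n_de: int = 30
    effect: float = 2.0
    noise_sd: float = 1.0
    mut_freq_luminal: float = 0.80
    mut_freq_basal: float = 0.15
    stage_mix: dict = field(default_factory=lambda: dict(DEFAULT_STAGE_MIX))
    housekeeping_genes: tuple[str, ...] = ("ACTB", "GAPDH")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_basal < 1 or self.n_luminal < 1:
            raise ValueError("n_basal and n_luminal must be >= 1")
        if not 0 <= self.n_de <= self.n_genes:
            raise ValueError("n_de must satisfy 0 <= n_de <= n_genes")
        for name in ("mut_freq_luminal", "mut_freq_basal"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.effect < 0:
            raise ValueError("effect must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        for grp, mix in self.stage_mix.items():
            if len(mix) != len(STAGES) or abs(sum(mix) - 1.0) > 1e-9:
                raise ValueError(f"stage_mix[{grp!r}] must be 3 proportions summing to 1")


@dataclass
class SyntheticCohort:
    """A generated cohort with its ground truth."""

    expression: ExpressionMatrix  # log2 scale, targets + housekeeping rows
    labels: pd.Series  # sample -> basal | luminal
    mutations: pd.DataFrame  # sample x gene, values mutant | wild-type
    stages: pd.Series  # sample -> NMIBC | MIBC | MET
    panel: PanelDefinition
    truth: CohortSpec
    true_effects: pd.Series  # gene -> signed log2 shift (basal minus luminal)
    baselines: pd.Series  # gene -> baseline log2 expression

    @property
    def samples(self) -> list[str]:
        return self.expression.samples


def default_panel(spec: CohortSpec) -> PanelDefinition:
    """Panel of n_genes targets (marker gene first) plus housekeeping genes."""
    targets = [MARKER_GENE] + [f"G{i:03d}" for i in range(2, spec.n_genes + 1)]
    return PanelDefinition(tuple(targets), tuple(spec.housekeeping_genes))


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw a cohort under ``spec``; deterministic given ``spec.seed``.

    Expression for gene g, sample s is
    ``baseline_g + sign_g * effect/2 + Normal(0, noise_sd)`` where sign_g is
    +1 for basal-up DE genes in basal samples, -1 in luminal samples (and
    the reverse for luminal-up genes), 0 for non-DE genes.  The marker gene
    is always the strongest luminal-up gene when any DE genes exist.
    Baselines are drawn once from Normal(0, 1) and recorded in the truth.
    """
    panel = default_panel(spec)
    rng = np.random.default_rng(spec.seed)
    genes = list(panel.all_genes)
    n_t = spec.n_genes
    samples = [f"B{i + 1:03d}" for i in range(spec.n_basal)] + [
        f"L{i + 1:03d}" for i in range(spec.n_luminal)
    ]
    labels = pd.Series(
        [BASAL] * spec.n_basal + [LUMINAL] * spec.n_luminal, index=samples, dtype=object
    )

    baselines = pd.Series(rng.normal(0.0, 1.0, size=len(genes)), index=genes)

    # signed true effects: basal-mean minus luminal-mean per gene
    effects = pd.Series(0.0, index=genes)
    if spec.n_de > 0:
        n_lum_up = (spec.n_de + 1) // 2  # marker gene included here
        n_bas_up = spec.n_de - n_lum_up
        lum_up = [MARKER_GENE] + [genes[1 + i] for i in range(n_lum_up - 1)]
        bas_up = [genes[n_lum_up + i] for i in range(n_bas_up)]
        effects[lum_up] = -spec.effect
        effects[bas_up] = spec.effect
        # marker gene carries the largest luminal-directed shift
        effects[MARKER_GENE] = -1.5 * spec.effect

    is_basal = (labels == BASAL).to_numpy()
    half = effects.to_numpy()[:, None] / 2.0
    mean = baselines.to_numpy()[:, None] + np.where(is_basal[None, :], half, -half)
    values = mean + rng.normal(0.0, spec.noise_sd, size=(len(genes), len(samples)))
    expr = ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), "log2")

    # marker-gene mutation status with group-specific frequency
    p_mut = np.where(is_basal, spec.mut_freq_basal, spec.mut_freq_luminal)
    mutant = rng.random(len(samples)) < p_mut
    mutations = pd.DataFrame(
        {MARKER_GENE: np.where(mutant, "mutant", "wild-type")}, index=samples
    )

    stages = pd.Series(index=samples, dtype=object)
    for grp in (BASAL, LUMINAL):
        mask = labels == grp
        stages[mask] = rng.choice(STAGES, size=int(mask.sum()), p=spec.stage_mix[grp])

    return SyntheticCohort(
        expression=expr,
        labels=labels,
        mutations=mutations,
        stages=stages,
        panel=panel,
        truth=spec,
        true_effects=effects,
        baselines=baselines,
    )


def encode_as_ct(
    cohort: SyntheticCohort,
    replicates: int = 3,
    failure_prob: float | dict[str, float] = 0.0,
    housekeeping_ct: float = 20.0,
    rep_sd: float = 0.25,
    seed: int = 0,
) -> CtTable:
    """Re-encode log2 expression as a replicate qPCR Ct table.

    Standard qPCR semantics: higher expression means lower Ct,
    ``Ct(s, g, rep) = housekeeping_ct - log2expr(s, g) + Normal(0, rep_sd)``.
    Each replicate is independently replaced by a failed reaction with its
    assay's failure probability.  Deterministic given ``seed``.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    genes = cohort.expression.genes
    if isinstance(failure_prob, dict):
        probs = {g: float(failure_prob.get(g, 0.0)) for g in genes}
    else:
        probs = {g: float(failure_prob) for g in genes}
    bad = {g: p for g, p in probs.items() if not 0.0 <= p <= 1.0}
    if bad:
        raise ValueError(f"failure probabilities must be in [0, 1]: {bad}")

    rng = np.random.default_rng(seed)
    x = cohort.expression.values  # genes x samples
    samples = cohort.expression.samples
    rows = []
    for gi, g in enumerate(genes):
        noise = rng.normal(0.0, rep_sd, size=(len(samples), replicates)) if rep_sd > 0 \
            else np.zeros((len(samples), replicates))
        fails = rng.random((len(samples), replicates)) < probs[g]
        for si, s in enumerate(samples):
            for r in range(replicates):
                ct = housekeeping_ct - x[gi, si] + noise[si, r]
                failed = bool(fails[si, r])
                rows.append((s, g, r + 1, np.nan if failed else ct, failed))
    rec = pd.DataFrame(rows, columns=list(CtTable.COLUMNS))
    # Ct values must be positive; shift cannot occur for sane housekeeping_ct,
    # but clip guards degenerate configurations.
    low = rec["ct"] <= 0
    if low.any():
        raise ValueError(
            "encoded Ct values <= 0; raise housekeeping_ct above the expression range"
        )
    return CtTable(rec)
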