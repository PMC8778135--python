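"""Synthetic cohort generator with planted ground truth.

Emulates the structure of a three-group faecal 16S study (healthy controls
plus two patient groups, with Montreal-style subgroup labels), a panel of
binary lifestyle/diet questionnaire variables — some deliberately imbalanced
across groups — and overdispersed, zero-inflated taxon counts. Counts are
drawn from a zero-inflated negative binomial: with probability pi_t a
structural zero, otherwise NB with mean

    mu_tj = library_size_j * exp(beta0_t + group effects + variable effects)

and dispersion (NB size) k_t; a hurdle switch replaces the mixture zero
with a hurdle zero mass and a zero-truncated NB positive part. Confounding
is planted by giving a variable group-dependent "yes" probabilities AND a
taxon effect while that taxon carries no direct group effect — the pattern
the downstream two-model comparison is designed to detect.

Every random draw's parameters are recorded in a :class:`GroundTruth`
ledger so recovery can be scored exactly.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import (
    CATEGORICAL, NUMERIC, CountTable, MetadataFrame, PhyloTree,
    TaxonomyTable, ValidationError, read_tree,
)

AGE_RANGE = (19.0, 72.0)  # truncation bounds for simulated ages

# Per-group "yes" probabilities for the default 16-variable questionnaire.
# dairy/fruit_veg/cereals/legumes are imbalanced between controls and cases.
DEFAULT_VARIABLES: dict[str, dict[str, float]] = {
    "dairy": {"HC": 0.70, "CD": 0.40, "UC": 0.35},
    "fruit_veg": {"HC": 0.80, "CD": 0.55, "UC": 0.50},
    "cereals": {"HC": 0.60, "CD": 0.30, "UC": 0.35},
    "legumes": {"HC": 0.55, "CD": 0.30, "UC": 0.30},
    "yogurt": {"HC": 0.50, "CD": 0.50, "UC": 0.50},
    "bread": {"HC": 0.75, "CD": 0.75, "UC": 0.75},
    "meat": {"HC": 0.70, "CD": 0.70, "UC": 0.70},
    "fish": {"HC": 0.45, "CD": 0.45, "UC": 0.45},
    "eggs": {"HC": 0.50, "CD": 0.50, "UC": 0.50},
    "sweets": {"HC": 0.40, "CD": 0.40, "UC": 0.40},
    "coffee": {"HC": 0.65, "CD": 0.65, "UC": 0.65},
    "alcohol": {"HC": 0.35, "CD": 0.35, "UC": 0.35},
    "smoking": {"HC": 0.25, "CD": 0.25, "UC": 0.25},
    "physical_activity": {"HC": 0.50, "CD": 0.50, "UC": 0.50},
    "lost_5kg": {"HC": 0.15, "CD": 0.15, "UC": 0.15},
    "gained_5kg": {"HC": 0.15, "CD": 0.15, "UC": 0.15},
}

DEFAULT_GROUP_SIZES = {"HC": 42, "CD": 52, "UC": 58}
DEFAULT_SUBGROUPS = {
    "HC": {"HC": 42},
    "CD": {"B1": 27, "B2": 22, "B3": 3},
    "UC": {"E1": 9, "E2": 18, "E3": 28},
}


@dataclass
class SyntheticConfig:
    """All knobs of the generator; defaults mirror the emulated study."""

    group_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    subgroup_sizes: dict[str, dict[str, int]] | None = field(
        default_factory=lambda: {g: dict(d) for g, d in DEFAULT_SUBGROUPS.items()})
    n_taxa: int = 40
    # per-taxon parameters: scalars broadcast, arrays used as-is, None drawn
    baseline_logmean: float | list[float] | None = None  # drawn N(-6.5,1.5)
    dispersion: float | list[float] | None = None        # drawn U[0.3,2.0]
    zero_inflation: float | list[float] = 0.15
    zero_mode: str = "zinb"  # or "hurdle"
    group_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    var_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    variables: dict[str, dict[str, float]] = field(
        default_factory=lambda: {v: dict(p) for v, p in DEFAULT_VARIABLES.items()})
    age_by_group: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"HC": (45.0, 13.0), "CD": (44.0, 13.0),
                                 "UC": (46.0, 13.0)})
    library_meanlog: float = 10.0
    library_sdlog: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            if n < 2:
                raise ValidationError(f"group {g!r} needs >=2 samples")
        pi = np.atleast_1d(np.asarray(self.zero_inflation, dtype=float))
        if ((pi < 0) | (pi > 1)).any():
            raise ValidationError("zero_inflation must be in [0,1]")
        if self.dispersion is not None:
            k = np.atleast_1d(np.asarray(self.dispersion, dtype=float))
            if (k <= 0).any():
                raise ValidationError("dispersion must be > 0")
        if self.zero_mode not in ("zinb", "hurdle"):
            raise ValidationError(f"unknown zero_mode {self.zero_mode!r}")
        taxa = set(taxon_names(self.n_taxa))
        for t in list(self.group_effects) + list(self.var_effects):
            if t not in taxa:
                raise ValidationError(f"effect map references unknown taxon {t!r}")
        for t, eff in self.group_effects.items():
            for g in eff:
                if g not in self.group_sizes:
                    raise ValidationError(
                        f"group effect on {t!r} references unknown group {g!r}")
        for t, eff in self.var_effects.items():
            for v in eff:
                if v not in self.variables:
                    raise ValidationError(
                        f"variable effect on {t!r} references unknown variable {v!r}")

    # -- canonical study conditions -------------------------------------

    @classmethod
    def default(cls, seed: int = 0) -> "SyntheticConfig":
        """Cohort with group-driven, diet-driven and confounded taxa.

        Taxa 1-6 respond to disease group directly; taxon 7 is the planted
        confounded taxon (responds to the imbalanced "cereals" variable
        only); taxa 8-9 respond to balanced diet variables only; taxa 10-11
        respond to both group and a variable; the rest are inert. Direct
        effects skew negative in the patient groups, emulating the
        depletion of commensal families characteristic of dysbiosis (with
        one enriched family and one discordant between the two diseases).
        """
        names = taxon_names(40)
        group_effects = {
            names[0]: {"CD": 1.2, "UC": 1.0},
            names[1]: {"CD": -1.2, "UC": -1.0},
            names[2]: {"CD": -0.9, "UC": -0.9},
            names[3]: {"CD": -0.9, "UC": -1.1},
            names[4]: {"CD": -0.8, "UC": 1.0},
            names[5]: {"CD": -1.0, "UC": -0.8},
            names[9]: {"CD": -0.9, "UC": -0.9},
            names[10]: {"CD": -1.0, "UC": -0.9},
        }
        var_effects = {
            names[6]: {"cereals": 1.3},     # confounded: diet-only, imbalanced var
            names[7]: {"yogurt": 0.9},
            names[8]: {"bread": -0.9},
            names[9]: {"meat": 0.7},
            names[10]: {"coffee": -0.7},
        }
        return cls(group_effects=group_effects, var_effects=var_effects,
                   seed=seed)

    @classmethod
    def null(cls, n_per_group: int = 20, n_taxa: int = 40,
             seed: int = 0) -> "SyntheticConfig":
        """No planted effects and balanced variables everywhere."""
        variables = {v: {g: 0.5 for g in ("HC", "CD", "UC")}
                     for v in DEFAULT_VARIABLES}
        return cls(group_sizes={"HC": n_per_group, "CD": n_per_group,
                                "UC": n_per_group},
                   subgroup_sizes=None, n_taxa=n_taxa, variables=variables,
                   age_by_group={g: (45.0, 13.0) for g in ("HC", "CD", "UC")},
                   seed=seed)

    @classmethod
    def confounded(cls, n_per_group: int = 50, n_taxa: int = 12,
                   lfc: float = 2.5, seed: int = 0) -> "SyntheticConfig":
        """Minimal cohort for the confounded-taxon recovery scenario.

        One taxon responds only to the strongly group-imbalanced "cereals"
        variable (yes-probability 0.80 in controls vs 0.15 in cases), so
        its induced marginal group effect, lfc × Δp ≈ 1.6 log units, is at
        least as strong as the direct group effects (±1.2) planted on two
        reference taxa — the confounded taxon looks unambiguously
        group-associated until the model adjusts for diet. The remaining
        taxa are inert.
        """
        names = taxon_names(n_taxa)
        variables = {v: dict(p) for v, p in DEFAULT_VARIABLES.items()}
        variables["cereals"] = {"HC": 0.80, "CD": 0.15, "UC": 0.15}
        return cls(group_sizes={"HC": n_per_group, "CD": n_per_group,
                                "UC": n_per_group},
                   subgroup_sizes=None, n_taxa=n_taxa,
                   group_effects={names[0]: {"CD": 1.2, "UC": 1.2},
                                  names[1]: {"CD": -1.2, "UC": -1.2}},
                   var_effects={names[2]: {"cereals": lfc}},
                   variables=variables,
                   seed=seed)


@dataclass
class GroundTruth:
    """Ledger of every planted parameter and realized library size."""

    taxa: list[str]
    baseline_logmean: list[float]
    dispersion: list[float]
    zero_inflation: list[float]
    zero_mode: str
    group_effects: dict[str, dict[str, float]]
    var_effects: dict[str, dict[str, float]]
    variable_imbalance: dict[str, bool]
    library_sizes: dict[str, float]

    def group_responsive_taxa(self) -> set[str]:
        return {t for t, e in self.group_effects.items()
                if any(v != 0 for v in e.values())}

    def variable_responsive_taxa(self) -> set[str]:
        return {t for t, e in self.var_effects.items()
                if any(v != 0 for v in e.values())}

    def confounded_taxa(self) -> set[str]:
        """Taxa driven only by an imbalanced variable, with no group effect."""
        out = set()
        for t, eff in self.var_effects.items():
            if t in self.group_responsive_taxa():
                continue
            if any(self.variable_imbalance.get(v, False) and lfc != 0
                   for v, lfc in eff.items()):
                out.add(t)
        return out

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "GroundTruth":
        text = Path(source).read_text() if isinstance(source, Path) else source
        return cls(**json.loads(text))


def taxon_names(n_taxa: int) -> list[str]:
    return [f"fam{i + 1:03d}" for i in range(n_taxa)]


# ---------------------------------------------------------------------------
# tree generation
# ---------------------------------------------------------------------------

def generate_tree(n_taxa: int, seed: int) -> PhyloTree:
    """Random rooted bifurcating tree: Yule-type splits, Exp(1) branch lengths."""
    if n_taxa < 2:
        raise ValidationError("need at least 2 taxa for a tree")
    rng = np.random.default_rng(seed)
    names = taxon_names(n_taxa)
    # leaves as newick fragments; repeatedly join two random subtrees
    subtrees = [f"{name}:{rng.exponential():.6f}" for name in names]
    while len(subtrees) > 2:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        b = subtrees.pop(j)
        a = subtrees.pop(i)
        subtrees.append(f"({a},{b}):{rng.exponential():.6f}")
    newick = f"({subtrees[0]},{subtrees[1]});"
    return read_tree(io.StringIO(newick))


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _per_taxon(value, n_taxa: int, rng, draw) -> np.ndarray:
    if value is None:
        return draw(rng)
    arr = np.broadcast_to(np.atleast_1d(np.asarray(value, float)),
                          (n_taxa,)).copy()
    return arr


def generate_cohort(config: SyntheticConfig, seed: int | None = None
                    ) -> tuple[CountTable, MetadataFrame, TaxonomyTable,
                               PhyloTree, GroundTruth]:
    """Draw one cohort; fully deterministic given the (config, seed) pair."""
    seed = config.seed if seed is None else seed
    root = np.random.SeedSequence(seed)
    s_meta, s_counts, s_tree, s_params = root.spawn(4)
    rng_meta = np.random.default_rng(s_meta)
    rng_counts = np.random.default_rng(s_counts)
    rng_params = np.random.default_rng(s_params)
    n_taxa = config.n_taxa
    taxa = taxon_names(n_taxa)

    # --- metadata -------------------------------------------------------
    rows = []
    for group, n in config.group_sizes.items():
        sub_labels: list[str] = []
        if config.subgroup_sizes and group in config.subgroup_sizes:
            for lab, m in config.subgroup_sizes[group].items():
                sub_labels += [lab] * m
            if len(sub_labels) > n:
                raise ValidationError(
                    f"subgroup sizes for {group!r} sum to {len(sub_labels)}, "
                    f"more than the group size {n}")
            # clinical subtyping need not cover everyone
            sub_labels += ["unclassified"] * (n - len(sub_labels))
        else:
            sub_labels = [group] * n
        mu_age, sd_age = config.age_by_group.get(group, (45.0, 13.0))
        lo, hi = AGE_RANGE
        a, b = (lo - mu_age) / sd_age, (hi - mu_age) / sd_age
        ages = stats.truncnorm.rvs(a, b, loc=mu_age, scale=sd_age, size=n,
                                   random_state=rng_meta)
        genders = rng_meta.choice(["F", "M"], size=n)
        for i in range(n):
            rows.append({"group": group, "subgroup": sub_labels[i],
                         "age": round(float(ages[i]), 1),
                         "gender": genders[i]})
    meta_df = pd.DataFrame(rows)
    meta_df.index = [f"S{i + 1:03d}" for i in range(len(meta_df))]
    for var, probs in config.variables.items():
        p = meta_df["group"].map(probs).to_numpy(dtype=float)
        meta_df[var] = np.where(rng_meta.random(len(meta_df)) < p, "yes", "no")
    schema = {"group": CATEGORICAL, "subgroup": CATEGORICAL,
              "age": NUMERIC, "gender": CATEGORICAL}
    schema.update({v: CATEGORICAL for v in config.variables})
    meta = MetadataFrame(meta_df, schema, target="group", subgroup="subgroup")
    # pin level order so HC-first reference coding survives any later reorder
    meta.levels["group"] = list(config.group_sizes)
    for v in config.variables:
        meta.levels[v] = ["no", "yes"]

    # --- per-taxon parameters ------------------------------------------
    beta0 = _per_taxon(config.baseline_logmean, n_taxa, rng_params,
                       lambda r: r.normal(-6.5, 1.5, n_taxa))
    disp = _per_taxon(config.dispersion, n_taxa, rng_params,
                      lambda r: r.uniform(0.3, 2.0, n_taxa))
    pi = _per_taxon(config.zero_inflation, n_taxa, rng_params, None)

    # --- counts ---------------------------------------------------------
    n_samples = len(meta_df)
    lib = np.exp(rng_counts.normal(config.library_meanlog,
                                   config.library_sdlog, n_samples))
    log_mu = np.tile(beta0[:, None], (1, n_samples)) + np.log(lib)[None, :]
    group_arr = meta_df["group"].to_numpy()
    for t, eff in config.group_effects.items():
        ti = taxa.index(t)
        for g, lfc in eff.items():
            log_mu[ti, group_arr == g] += lfc
    for t, eff in config.var_effects.items():
        ti = taxa.index(t)
        for v, lfc in eff.items():
            log_mu[ti, (meta_df[v] == "yes").to_numpy()] += lfc
    mu = np.exp(log_mu)
    k = disp[:, None]
    counts = rng_counts.negative_binomial(k, k / (k + mu))
    if config.zero_mode == "zinb":
        counts = np.where(rng_counts.random(counts.shape) < pi[:, None],
                          0, counts)
    else:  # hurdle: zero mass pi, positives from zero-truncated NB
        p_nb = k / (k + mu)
        p0 = stats.nbinom.cdf(0, k, p_nb)
        u = rng_counts.uniform(p0, 1.0)  # maps to the positive NB tail
        positives = stats.nbinom.ppf(u, k, p_nb).astype(np.int64)
        positives = np.maximum(positives, 1)
        counts = np.where(rng_counts.random(counts.shape) < pi[:, None],
                          0, positives)
    table = CountTable(pd.DataFrame(counts, index=taxa,
                                    columns=meta_df.index))

    # --- taxonomy + tree ------------------------------------------------
    phyla = [f"p__P{(i % 4) + 1}" for i in range(n_taxa)]
    tax = TaxonomyTable(pd.DataFrame(
        {"kingdom": "k__Bacteria", "phylum": phyla,
         "family": [f"f__{t}" for t in taxa]}, index=taxa))
    tree = generate_tree(n_taxa, int(s_tree.generate_state(1)[0] % (2**31)))

    imbalance = {v: len({round(p, 12) for p in probs.values()}) > 1
                 for v, probs in config.variables.items()}
    truth = GroundTruth(
        taxa=taxa,
        baseline_logmean=[float(b) for b in beta0],
        dispersion=[float(d) for d in disp],
        zero_inflation=[float(p) for p in pi],
        zero_mode=config.zero_mode,
        group_effects={t: dict(e) for t, e in config.group_effects.items()},
        var_effects={t: dict(e) for t, e in config.var_effects.items()},
        variable_imbalance=imbalance,
        library_sizes={s: float(l) for s, l in zip(meta_df.index, lib)},
    )
    return table, meta, tax, tree, truth
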