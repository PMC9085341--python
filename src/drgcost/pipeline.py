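"""End-to-end orchestration: clean -> derive -> composition -> premise ->
univariate screen -> gamma fit -> tree grouping (E-CHAID and CART) ->
comparison -> validation -> payment standards.

``run_pipeline`` is a pure function of (input data, configuration, seed):
every report it writes is re-derivable from the persisted intermediates and
two runs with the same inputs produce byte-identical output (no timestamps
in any artifact).  If the parent group's CV is not above 1, subdivision is
not indicated and the grouping/validation/payment stages are skipped and
reported as such.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import records as rec
from . import synthetic as syn
from .errors import ConfigurationError, PipelineError
from .glm import GammaFit, ModelSpec, fit_gamma
from .tree import TreeConfig, TreeModel, compare_models, comparison_table, grow_cart, grow_tree
from .univariate import los_summary, percentage, screen_factors, univariate_table
from .validation import payment_standard, payment_table, premise_check, validate_grouping

__all__ = [
    "PipelineConfig",
    "CompositionReport",
    "RunResult",
    "composition_report",
    "run_pipeline",
]


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one input source: a delimited cohort file (with the CC tables
    and scheme-code file alongside in ``cc_dir``) or the synthetic
    generator (``generator`` or plain ``n``/``seed``).
    """

    outdir: str | Path = "run"
    source: str | Path | None = None  # cohort CSV; None -> synthetic
    cc_dir: str | Path | None = None  # inclusion.csv / exclusion.csv / scheme.csv
    generator: syn.GeneratorConfig | None = None
    n: int = 5204
    seed: int = 0
    los_max: int = 60
    #: "auto": percentile-trim file sources at (1, 99); skip the trim for
    #: synthetic cohorts, which emulate an already-trimmed cohort.
    trim: tuple[float, float] | None | str = "auto"
    alpha: float = 0.05
    spec: ModelSpec = field(default_factory=ModelSpec)
    echaid: TreeConfig = field(default_factory=TreeConfig)
    cart: TreeConfig = field(default_factory=lambda: TreeConfig(algorithm="cart"))
    precision: int = 2

    def __post_init__(self):
        if self.source is not None and self.generator is not None:
            raise ConfigurationError("choose one input source: file or synthetic")
        if self.source is not None and self.cc_dir is None:
            raise ConfigurationError("a file source needs cc_dir")
        if self.source is None and self.generator is None:
            self.generator = syn.default_config(n=self.n, seed=self.seed)
        if self.trim == "auto":
            self.trim = (1.0, 99.0) if self.source is not None else None

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "source": None if self.source is None else str(self.source),
            "cc_dir": None if self.cc_dir is None else str(self.cc_dir),
            "n": self.n,
            "seed": self.seed,
            "los_max": self.los_max,
            "trim": None if self.trim is None else list(self.trim),
            "alpha": self.alpha,
            "spec": {"factors": dict(self.spec.factors), "response": self.spec.response},
            "echaid": dataclasses.asdict(self.echaid),
            "cart": dataclasses.asdict(self.cart),
            "precision": self.precision,
            "generator": None
            if self.generator is None
            else {
                k: v
                for k, v in dataclasses.asdict(self.generator).items()
                if k in ("n", "seed", "n_codes", "target_mean", "target_cv")
            },
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        kwargs: dict = {}
        for key in ("source", "cc_dir", "n", "seed", "los_max",
                    "alpha", "precision"):
            if key in raw and raw[key] is not None:
                kwargs[key] = raw[key]
        if "trim" in raw:
            kwargs["trim"] = tuple(raw["trim"]) if raw["trim"] else None
        if raw.get("spec"):
            kwargs["spec"] = ModelSpec(**raw["spec"])
        if raw.get("echaid"):
            kwargs["echaid"] = TreeConfig(**raw["echaid"])
        if raw.get("cart"):
            kwargs["cart"] = TreeConfig(**raw["cart"])
        if raw.get("generator"):
            kwargs["generator"] = syn.GeneratorConfig(**raw["generator"])
        return cls(**kwargs)


@dataclass
class CompositionReport:
    """Per-year cost-component means and shares, plus grand totals."""

    table: pd.DataFrame  # index: component, columns: (year, mean|share_pct)
    year_overall: pd.Series  # mean total cost per year
    year_n: pd.Series
    total_spend: float  # sum of all costs over all years

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out.columns = [f"{year}_{stat}" for year, stat in out.columns]
        return out.reset_index()


def composition_report(cohort: pd.DataFrame) -> CompositionReport:
    """Cost composition by admission year: a component's share is its mean
    divided by that year's overall mean cost, in percent."""
    if "admission_year" not in cohort.columns:
        raise ConfigurationError("cohort lacks admission_year")
    comp_cols = [f"cost_{c}" for c in rec.COST_COMPONENTS]
    by_year = cohort.groupby("admission_year")
    year_overall = by_year["total_cost"].mean()
    year_n = by_year.size()
    blocks = {}
    for year, sub in by_year:
        means = sub[comp_cols].mean()
        means.index = [c.removeprefix("cost_") for c in comp_cols]
        shares = means.map(lambda m: percentage(m, year_overall[year]))
        blocks[(year, "mean")] = means
        blocks[(year, "share_pct")] = shares
    table = pd.DataFrame(blocks)
    table.columns = pd.MultiIndex.from_tuples(table.columns)
    return CompositionReport(
        table=table,
        year_overall=year_overall,
        year_n=year_n,
        total_spend=float(cohort["total_cost"].sum()),
    )


@dataclass
class RunResult:
    outdir: Path
    cohort: pd.DataFrame
    exclusion_log: rec.ExclusionLog
    premise: object
    composition: CompositionReport
    univariate: list
    gamma: GammaFit | None
    echaid: TreeModel | None
    cart: TreeModel | None
    payments: list | None
    validation: object | None
    grouped: bool


def _fmt(frame: pd.DataFrame, path: Path, precision: int) -> None:
    frame.to_csv(path, index=False, float_format=f"%.{precision}f")


def run_pipeline(config: PipelineConfig) -> RunResult:
    """Execute every stage and persist all artifacts under ``config.outdir``.

    Raises :class:`PipelineError` naming the stage on failure; partial
    outputs written before the failure are left in place.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(stage: str, message: str) -> None:
        log_lines.append(f"[{stage}] {message}")

    def flush_log() -> None:
        (outdir / "log.txt").write_text("\n".join(log_lines) + "\n")

    stage = "configure"
    try:
        config.to_yaml(outdir / "config.yaml")

        stage = "acquire"
        if config.source is None:
            gen = config.generator
            table, universe = syn.generate_cc_tables(seed=gen.seed, n_codes=gen.n_codes)
            raw = syn.generate_cohort(gen, table, universe)
            scheme = universe.scheme_codes
            cc_dir = outdir / "cc_tables"
            cc_dir.mkdir(exist_ok=True)
            rec.write_cc_tables(table, cc_dir / "inclusion.csv", cc_dir / "exclusion.csv")
            rec.write_scheme_codes(scheme, cc_dir / "scheme.csv")
            rec.write_records(raw, outdir / "cohort_raw.csv")
            log(stage, f"synthetic cohort generated: n={len(raw)} seed={gen.seed}")
        else:
            parsed = rec.read_records(config.source)
            raw = parsed.records
            cc_dir = Path(config.cc_dir)
            table = rec.read_cc_tables(cc_dir / "inclusion.csv", cc_dir / "exclusion.csv")
            scheme = rec.read_scheme_codes(cc_dir / "scheme.csv")
            log(stage, f"read {len(raw)} records ({len(parsed.issues)} row issues)")

        stage = "clean"
        retained, xlog = rec.apply_exclusions(
            raw, scheme, los_max=config.los_max, trim=config.trim
        )
        xlog.to_json(outdir / "exclusion_log.json")
        log(stage, f"in={xlog.input_n} out={xlog.retained_n} excluded={xlog.counts}")

        stage = "derive"
        cohort = rec.cohort_frame(retained, table)
        _fmt(cohort, outdir / "cohort_clean.csv", config.precision)
        log(stage, f"features derived for {len(cohort)} records")

        stage = "composition"
        comp = composition_report(cohort)
        _fmt(comp.to_frame(), outdir / "composition.csv", config.precision)
        log(stage, f"total spend={comp.total_spend:.2f}")

        stage = "premise"
        premise = premise_check(cohort["total_cost"])
        (outdir / "premise.json").write_text(
            json.dumps({"cv": round(premise.cv, 4), "subdivide": premise.subdivide})
            + "\n"
        )
        log(stage, f"cohort CV={premise.cv:.4f} subdivide={premise.subdivide}")

        stage = "univariate"
        uni = screen_factors(cohort, alpha=config.alpha)
        uni_frame = univariate_table(uni, los_mean_sd=los_summary(cohort))
        uni_frame.to_csv(outdir / "univariate.csv", index=False, float_format="%.4g")
        log(stage, f"{sum(bool(r.significant) for r in uni)}/{len(uni)} factors significant")

        stage = "gamma"
        gamma = fit_gamma(cohort, spec=config.spec)
        _fmt(gamma.table.reset_index(), outdir / "gamma.csv", config.precision)
        log(stage, f"dispersion={gamma.dispersion:.4f}")

        if not premise.subdivide:
            log("grouping", "not indicated (CV <= 1); stages skipped")
            flush_log()
            return RunResult(
                outdir, cohort, xlog, premise, comp, uni, gamma,
                None, None, None, None, grouped=False,
            )

        stage = "grouping"
        echaid = grow_tree(cohort, config.echaid)
        cart = grow_cart(cohort, config.cart)
        echaid.to_json(outdir / "tree_echaid.json")
        cart.to_json(outdir / "tree_cart.json")
        leaf = echaid.apply(cohort)
        grouped = cohort.copy()
        grouped["group"] = leaf
        _fmt(grouped, outdir / "cohort_grouped.csv", config.precision)
        log(stage, f"e-chaid leaves={echaid.n_leaves} cart leaves={cart.n_leaves}")

        stage = "comparison"
        comparisons = compare_models([echaid, cart], cohort)
        _fmt(comparison_table(comparisons), outdir / "comparison.csv", 3)
        log(stage, "; ".join(
            f"{c.model}: r={c.correlation:.3f} mae={c.mae:.1f} groups={c.n_groups}"
            for c in comparisons
        ))

        stage = "validation"
        val = validate_grouping(grouped["total_cost"], leaf, alpha=config.alpha)
        payload = {
            "n_groups": val.n_groups,
            "n_cv_le_1": val.n_homogeneous,
            "singletons": val.singleton_groups,
            "kruskal_h": round(val.kruskal.statistic, 3),
            "kruskal_p": val.kruskal.p_value,
            "group_cv": {str(k): round(v, 4) for k, v in val.group_cv.items()},
        }
        (outdir / "validation.json").write_text(json.dumps(payload, indent=2) + "\n")
        log(stage, f"{val.n_homogeneous}/{val.n_groups} groups with CV<=1; "
                   f"KW p={val.kruskal.p_value:.3g}")

        stage = "payment"
        labels = echaid.leaf_labels()
        payments = []
        for i, nid in enumerate(echaid.leaf_ids, start=1):
            sub = grouped.loc[grouped["group"] == nid, "total_cost"]
            payments.append(
                payment_standard(sub, group_id=str(i), description=labels[nid])
            )
        _fmt(payment_table(payments), outdir / "payment.csv", config.precision)
        log(stage, f"{len(payments)} group payment standards written")

        flush_log()
        return RunResult(
            outdir, cohort, xlog, premise, comp, uni, gamma,
            echaid, cart, payments, val, grouped=True,
        )
    except Exception as exc:
        log(stage, f"FAILED: {exc}")
        flush_log()
        if isinstance(exc, (PipelineError, ConfigurationError)):
            raise
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
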