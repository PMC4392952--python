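"""End-to-end study emulation.

generate cohort -> section -> estimate volumes (Cavalieri) and apoptotic
densities (physical dissector) -> response-index table, fitted curves and
critical point -> group statistics, all under one seeded configuration
producing a single reproducible report.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cavalieri, dissector, indices, stats
from .phantom import (
    GROUPS,
    REGIONS,
    AnimalPhantom,
    GroupParameters,
    _load_fixture,
    default_group_parameters,
    make_cohort,
    section_phantom,
    truth_table,
)

log = logging.getLogger("hippostereo")

_QUANTITIES = ("V_DG", "V_CA3", "ND_DG", "ND_CA3", "BG", "Cu")


@dataclass
class RunConfig:
    """All knobs of one study emulation run.

    Thicknesses follow the study design: 10 um sections for volume
    estimation, 5 um sections (and a 5 um dissector interval) for
    apoptosis counting.
    """

    n_per_group: int = 10
    seed: int = 0
    volume_thickness_mm: float = 0.010
    apoptosis_thickness_mm: float = 0.005
    cavalieri_period: int = 10
    grid_spacing_mm: float = 0.1
    dissector_interval_mm: float = 0.005
    frame_size_mm: float = 0.1
    n_frames: int = 300
    pair_period: int = 10
    index_mode: str = "per_animal"
    curve_degree: int = 1
    outdir: str | None = None
    group_parameters: GroupParameters = field(default_factory=default_group_parameters)

    def validate(self) -> None:
        positives = (
            self.volume_thickness_mm,
            self.apoptosis_thickness_mm,
            self.cavalieri_period,
            self.grid_spacing_mm,
            self.dissector_interval_mm,
            self.frame_size_mm,
            self.n_frames,
            self.pair_period,
            self.n_per_group,
        )
        if any(v <= 0 for v in positives):
            raise ValueError("all physical and sampling settings must be positive")
        self.group_parameters.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gp_raw = raw.pop("group_parameters", None)
        cfg = cls(**raw)
        if gp_raw is not None:
            gp = default_group_parameters()
            for name in ("volume", "density", "blood_glucose", "plasma_cu"):
                if name in gp_raw:
                    setattr(gp, name, gp_raw[name])
            if "correlation" in gp_raw:
                gp.correlation = np.asarray(gp_raw["correlation"], dtype=float)
            if "trunc_floor_frac" in gp_raw:
                gp.trunc_floor_frac = float(gp_raw["trunc_floor_frac"])
            cfg.group_parameters = gp
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        gp = d.pop("group_parameters")
        gp["correlation"] = np.asarray(gp["correlation"]).tolist()
        d["group_parameters"] = gp
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclass
class StudyReport:
    """Everything one run produces, with full audit trails."""

    config: RunConfig
    animals: pd.DataFrame  # per-animal estimates + truth + audit counts
    group_summary: pd.DataFrame  # mean +/- SD per group per quantity
    index_table_per_animal: indices.ResponseIndexTable
    index_table_ratio_of_means: indices.ResponseIndexTable
    curves: dict[str, indices.IndexCurve] | None
    critical: indices.CriticalPoint | None
    critical_error: str | None
    statistics: dict
    recovery: pd.DataFrame  # estimated group means vs configured truth
    errors: list[str] = field(default_factory=list)

    def save(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.animals.to_csv(out / "animals.csv", index=False)
        self.group_summary.to_csv(out / "group_summary.csv")
        self.index_table_per_animal.means.to_csv(out / "index_means_per_animal.csv")
        self.index_table_per_animal.sds.to_csv(out / "index_sds_per_animal.csv")
        self.index_table_ratio_of_means.means.to_csv(out / "index_means_ratio_of_means.csv")
        self.recovery.to_csv(out / "recovery.csv", index=False)
        payload = {
            "curves": {
                k: {"coeffs": list(c.coeffs), "equation": c.equation()}
                for k, c in (self.curves or {}).items()
            },
            "critical_point": (
                {"x_star": self.critical.x_star, "y_star": self.critical.y_star}
                if self.critical
                else None
            ),
            "critical_error": self.critical_error,
            "statistics": self.statistics,
            "errors": self.errors,
        }
        with open(out / "report.json", "w") as fh:
            json.dump(payload, fh, indent=1)
        self.config.to_yaml(out / "config.yaml")

    def to_json(self) -> str:
        """Canonical JSON form of the report (used for determinism checks)."""
        return json.dumps(
            {
                "animals": self.animals.to_dict(orient="list"),
                "group_summary": self.group_summary.to_dict(),
                "index_per_animal": self.index_table_per_animal.means.to_dict(),
                "index_ratio_of_means": self.index_table_ratio_of_means.means.to_dict(),
                "curves": {k: list(c.coeffs) for k, c in (self.curves or {}).items()},
                "critical": dataclasses.asdict(self.critical) if self.critical else None,
                "statistics": self.statistics,
            },
            sort_keys=True,
        )


def measure_cohort(cohort: list[AnimalPhantom], config: RunConfig, seed: int) -> pd.DataFrame:
    """Run both estimators on every animal; returns the per-animal table."""
    rng = np.random.default_rng(seed)
    rows = []
    for animal in cohort:
        row: dict = {"animal_id": animal.animal_id, "group": animal.group}
        stack_v = section_phantom(animal, config.volume_thickness_mm)
        for region in REGIONS:
            est = cavalieri.estimate_region_volume(
                stack_v,
                region,
                period=config.cavalieri_period,
                grid_spacing=config.grid_spacing_mm,
                seed=rng,
            )
            row[f"V_{region}"] = est.volume
            row[f"sum_p_{region}"] = est.sum_p
        has_markers = any(len(animal.markers[r]) for r in REGIONS)
        if has_markers:
            stack_d = section_phantom(animal, config.apoptosis_thickness_mm)
            for region in REGIONS:
                est_d = dissector.estimate_density(
                    stack_d,
                    region,
                    interval=config.dissector_interval_mm,
                    frame_size=config.frame_size_mm,
                    n_frames=config.n_frames,
                    seed=rng,
                    pair_period=config.pair_period,
                )
                row[f"ND_{region}"] = est_d.density
                row[f"sum_q_{region}"] = est_d.sum_q
                row[f"sum_frames_{region}"] = est_d.sum_frames
        else:
            for region in REGIONS:
                row[f"ND_{region}"] = 0.0
                row[f"sum_q_{region}"] = 0
                row[f"sum_frames_{region}"] = 0
        row["BG"] = animal.covariates["blood_glucose"]
        row["Cu"] = animal.covariates["plasma_cu"]
        rows.append(row)
    return pd.DataFrame(rows)


def _group_summary(animals: pd.DataFrame) -> pd.DataFrame:
    records = []
    for group in GROUPS:
        sub = animals[animals["group"] == group]
        rec = {"group": group}
        for q in _QUANTITIES:
            rec[f"{q}_mean"] = float(sub[q].mean())
            rec[f"{q}_sd"] = float(sub[q].std(ddof=1)) if len(sub) > 1 else 0.0
        records.append(rec)
    return pd.DataFrame(records).set_index("group")


def run_study(config: RunConfig) -> StudyReport:
    """Execute the full emulation and assemble the report."""
    config.validate()
    master = np.random.default_rng(config.seed)
    cohort_seed, measure_seed = (int(s) for s in master.integers(0, 2**31 - 1, size=2))
    log.info("generating cohort: %d animals/group, seed=%d", config.n_per_group, cohort_seed)
    cohort = make_cohort(config.group_parameters, config.n_per_group, cohort_seed)
    truth = truth_table(cohort)

    log.info("estimating volumes and densities")
    animals = measure_cohort(cohort, config, measure_seed)
    animals = animals.merge(
        truth[["animal_id", "true_V_DG", "true_V_CA3", "true_ND_DG", "true_ND_CA3"]],
        on="animal_id",
    )
    summary = _group_summary(animals)

    errors: list[str] = []
    table_pa = None
    try:
        table_pa = indices.index_table(animals, mode="per_animal")
    except ValueError as exc:
        errors.append(f"indices/per_animal: {exc}")
    table_rm = indices.index_table(animals, mode="ratio_of_means") if _denominators_ok(
        animals
    ) else None
    if table_rm is None:
        errors.append("indices/ratio_of_means: zero group-mean denominator")

    curves = None
    critical = None
    critical_error = None
    table_for_curves = table_pa if config.index_mode == "per_animal" else table_rm
    if table_for_curves is not None:
        try:
            curves = {
                which: indices.fit_index_curve(table_for_curves, which, config.curve_degree)
                for which in indices.INDEX_NAMES
            }
            critical = indices.critical_point(curves["volume"], curves["density"])
        except (ValueError, ArithmeticError) as exc:
            critical_error = str(exc)

    log.info("running group statistics")
    stats_report = {}
    for q in _QUANTITIES:
        try:
            samples = [
                animals.loc[animals["group"] == g, q].to_numpy(dtype=float) for g in GROUPS
            ]
            cmp = stats.group_comparison(samples, labels=GROUPS)
            stats_report[q] = {
                "F": cmp.f_statistic,
                "p": cmp.p_value,
                "tukey": [dataclasses.asdict(t) for t in cmp.pairwise],
            }
        except ValueError as exc:
            stats_report[q] = {"error": str(exc)}
            errors.append(f"stats/{q}: {exc}")
    try:
        stats_report["correlations"] = stats.correlation_matrix(
            animals, ["V_DG", "V_CA3", "ND_DG", "ND_CA3", "BG", "Cu"]
        ).to_dict(orient="records")
    except ValueError as exc:
        stats_report["correlations"] = {"error": str(exc)}
        errors.append(f"stats/correlations: {exc}")

    recovery = _recovery_table(summary, config.group_parameters)
    placeholder = table_pa if table_pa is not None else table_rm
    report = StudyReport(
        config=config,
        animals=animals,
        group_summary=summary,
        index_table_per_animal=placeholder,
        index_table_ratio_of_means=table_rm if table_rm is not None else placeholder,
        curves=curves,
        critical=critical,
        critical_error=critical_error,
        statistics=stats_report,
        recovery=recovery,
        errors=errors,
    )
    if config.outdir:
        report.save(config.outdir)
    return report


def _denominators_ok(animals: pd.DataFrame) -> bool:
    for group in GROUPS:
        sub = animals[animals["group"] == group]
        if sub["V_CA3"].mean() <= 0 or sub["ND_CA3"].mean() <= 0:
            return False
    return True


def _recovery_table(summary: pd.DataFrame, params: GroupParameters) -> pd.DataFrame:
    rows = []
    for group in GROUPS:
        truth = params.group_means(group)
        for q in ("V_DG", "V_CA3", "ND_DG", "ND_CA3"):
            est = float(summary.loc[group, f"{q}_mean"])
            true = truth[q]
            rows.append(
                {
                    "group": group,
                    "quantity": q,
                    "estimated_mean": est,
                    "configured_truth": true,
                    "relative_error": (est - true) / true if true else np.nan,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# published-table reproduction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Table1Reproduction:
    """Ratio-of-means response-index table vs the published cells."""

    table: indices.ResponseIndexTable
    published: pd.DataFrame
    mismatches: tuple[tuple[str, str], ...]  # (index name, group) cells differing at 2 dp

    @property
    def flags(self) -> list[str]:
        return [
            f"{which}/{group}: ratio-of-means {self.table.cell(which, group, 2):.2f} "
            f"differs from published {float(self.published.loc[which, group]):.2f} "
            "(per-animal ratio data unpublished)"
            for which, group in self.mismatches
        ]


def reproduce_table1() -> Table1Reproduction:
    """Recompute the published response-index table from the printed group means.

    Uses the packaged fixture of per-group mean volumes and densities,
    computes DG/CA3 ratios of group means at 2-dp rounding, and flags any
    cell where that computation disagrees with the published table (which
    was built from unpublished per-animal ratios).
    """
    fx = _load_fixture()
    group_means = {
        "volume": {r: {g: fx["volume_mm3"][r][g][0] for g in GROUPS} for r in REGIONS},
        "density": {r: {g: fx["density_per_mm3"][r][g][0] for g in GROUPS} for r in REGIONS},
    }
    table = indices.index_table_from_group_means(group_means)
    published = pd.DataFrame(fx["published_response_index"]).T.loc[
        list(indices.INDEX_NAMES), list(GROUPS)
    ]
    mismatches = []
    for which in indices.INDEX_NAMES:
        for group in GROUPS:
            if table.cell(which, group, 2) != round(float(published.loc[which, group]), 2):
                mismatches.append((which, group))
    return Table1Reproduction(table=table, published=published, mismatches=tuple(mismatches))


# ---------------------------------------------------------------------------
# replicated power check
# ---------------------------------------------------------------------------

def dg_volume_group_effect_rate(
    n_replicates: int,
    seed: int,
    config: RunConfig | None = None,
    alpha: float = 0.05,
) -> float:
    """Fraction of simulated studies where ANOVA detects the DG-volume group effect.

    Each replicate regenerates the four-arm cohort and re-estimates DG
    volumes by the Cavalieri pipeline; markers are not seeded since they
    cannot influence volume estimation.
    """
    config = config or RunConfig()
    rng = np.random.default_rng(seed)
    detected = 0
    for _ in range(n_replicates):
        s1, s2 = (int(v) for v in rng.integers(0, 2**31 - 1, size=2))
        cohort = make_cohort(config.group_parameters, config.n_per_group, s1, with_markers=False)
        sub_rng = np.random.default_rng(s2)
        volumes: dict[str, list[float]] = {g: [] for g in GROUPS}
        for animal in cohort:
            stack = section_phantom(animal, config.volume_thickness_mm)
            est = cavalieri.estimate_region_volume(
                stack,
                "DG",
                period=config.cavalieri_period,
                grid_spacing=config.grid_spacing_mm,
                seed=sub_rng,
            )
            volumes[animal.group].append(est.volume)
        res = stats.one_way_anova([volumes[g] for g in GROUPS])
        detected += res.p_value < alpha
    return detected / n_replicates
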