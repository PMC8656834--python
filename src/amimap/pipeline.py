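"""End-to-end orchestration: synthesize -> link -> disaggregate -> fit -> summarize.

Each stage reads and writes plain files inside the run directory, so any
stage can be re-run in isolation. A manifest records the configuration,
the root seed, stage audit counts and a checksum for every output file.
All randomness flows from one root seed, split per stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._common import ConfigError, validate_periods
from .event_linkage import aggregate_events, link_events
from .population_estimation import bland_altman, disaggregate_population, exclude_district
from .spatial_model import (
    MCMCConfig,
    build_adjacency,
    check_convergence,
    fit_all_strata,
    posterior_rate_table,
)
from .standardization import (
    StandardWeights,
    decile_classify,
    inequality_metrics,
    percent_change_table,
    standardized_township_rates,
    summarize_table1,
    summarize_table2,
)
from .synthetic_registry import (
    DupProbs,
    SyntheticConfig,
    generate_city,
    map_to_geojson,
    write_city,
)

log = logging.getLogger("amimap")


@dataclass
class RunConfig:
    """Configuration of one reproducible pipeline run."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    window_days: int = 28
    min_age: int = 35
    exclude: str | None = None  # district excluded in a sensitivity re-run
    seed: int = 0

    def __post_init__(self):
        # split the root seed per stage
        stage_seeds = np.random.SeedSequence(self.seed).generate_state(2) % (2**31)
        self.synthetic.seed = int(stage_seeds[0])
        self.mcmc.seed = int(stage_seeds[1])
        validate_periods(self.synthetic.periods)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        syn = dict(d.pop("synthetic", {}))
        if "dup_probs" in syn:
            syn["dup_probs"] = DupProbs(**syn["dup_probs"])
        if "periods" in syn:
            syn["periods"] = tuple(tuple(p) for p in syn["periods"])
        if "years" in syn:
            syn["years"] = tuple(syn["years"])
        mc = d.pop("mcmc", {})
        known = {"window_days", "min_age", "exclude", "seed"}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(
            synthetic=SyntheticConfig(**syn), mcmc=MCMCConfig(**mc), **{k: d[k] for k in d}
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_jsonable(self) -> dict:
        d = asdict(self)
        d["synthetic"]["baseline_log_rates"] = {
            f"{sex}|{age}": list(v)
            for (sex, age), v in self.synthetic.baseline_log_rates.items()
        }
        return d


def _setup_logging(outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    log.setLevel(logging.INFO)
    log.handlers = [h for h in log.handlers if not isinstance(h, logging.FileHandler)]
    fh = logging.FileHandler(outdir / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    if not any(isinstance(h, logging.StreamHandler) for h in log.handlers):
        log.addHandler(logging.StreamHandler())


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_summaries(
    outdir: Path,
    rate_table: pd.DataFrame,
    map_,
    standard: StandardWeights,
    age_groups,
) -> dict[str, Path]:
    """Stage 5: publication-shaped tables, deciles, percent changes."""
    paths = {}
    t1 = summarize_table1(rate_table, standard, age_groups)
    t2 = summarize_table2(rate_table, standard, age_groups)
    paths["table1"] = outdir / "table1.csv"
    paths["table2"] = outdir / "table2.csv"
    t1.to_csv(paths["table1"], index=False)
    t2.to_csv(paths["table2"], index=False)

    std = standardized_township_rates(rate_table, standard)
    dec_frames = []
    for period, sub in std.groupby("period"):
        d = decile_classify(sub.set_index("township_id")["rate"])
        dec_frames.append(
            pd.DataFrame(
                {
                    "township_id": d.index,
                    "period": period,
                    "rate": sub.set_index("township_id")["rate"].reindex(d.index).round(1),
                    "decile": d.to_numpy(),
                    "high_rate": d.to_numpy() == 10,
                }
            )
        )
    deciles = pd.concat(dec_frames, ignore_index=True)
    paths["deciles"] = outdir / "deciles.csv"
    deciles.to_csv(paths["deciles"], index=False)

    last = sorted(std["period"].unique())[-1]
    props = (
        deciles[deciles["period"] == last]
        .set_index("township_id")[["rate", "decile", "high_rate"]]
        .rename(columns={"decile": f"decile_{last}"})
    )
    paths["geojson"] = outdir / "deciles.geojson"
    with open(paths["geojson"], "w") as fh:
        json.dump(map_to_geojson(map_, props), fh)

    pc = percent_change_table(rate_table, standard, age_groups)
    paths["percent_change"] = outdir / "percent_change.csv"
    pc.to_csv(paths["percent_change"], index=False)
    return paths


def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Execute all stages; returns the run directory.

    Any stage failure raises with the stage name in the message. Outputs
    are deterministic functions of (config, seed).
    """
    out = Path(outdir)
    _setup_logging(out)
    timings: dict[str, float] = {}
    manifest: dict = {"config": config.to_jsonable(), "seed": config.seed}
    paths: dict[str, Path] = {}

    current = {"stage": "setup"}

    def stage(name):
        log.info("stage %s starting", name)
        current["stage"] = name
        timings[name] = time.time()

    def done(name):
        timings[name] = round(time.time() - timings[name], 2)
        log.info("stage %s done in %.1fs", name, timings[name])

    try:
        stage("synthesize")
        city = generate_city(config.synthetic)
        paths.update(write_city(city, out / "inputs"))
        done("synthesize")

        map_ = city.map
        if config.exclude is not None:
            map_, _, _ = exclude_district(config.exclude, city.map)
            manifest["excluded_district"] = config.exclude
            log.info("excluding district %s: %d townships remain", config.exclude, map_.n)

        stage("link")
        res = link_events(
            city.hospital, city.deaths, window_days=config.window_days, min_age=config.min_age
        )
        kept_events = res.events[res.events["township_id"].isin(set(map_.townships))]
        counts = aggregate_events(
            kept_events,
            map_.townships,
            periods=config.synthetic.periods,
            age_groups=config.synthetic.age_groups,
            sexes=config.synthetic.sexes,
        )
        paths["events"] = out / "events.csv"
        kept_events.to_csv(paths["events"], index=False)
        paths["counts"] = out / "counts.csv"
        counts.to_csv(paths["counts"], index=False)
        paths["linkage_audit"] = out / "linkage_audit.json"
        with open(paths["linkage_audit"], "w") as fh:
            json.dump(res.audit.to_dict(), fh, indent=2)
        manifest["linkage_audit"] = res.audit.to_dict()
        done("link")

        stage("disaggregate")
        person_years = disaggregate_population(
            city.population.township_year_sex,
            city.population.district_age_sex,
            city.map.district_of,
            periods=config.synthetic.periods,
        )
        person_years = person_years[
            person_years["township_id"].isin(set(map_.townships))
        ].reset_index(drop=True)
        paths["person_years"] = out / "person_years.csv"
        person_years.to_csv(paths["person_years"], index=False)
        if len(set(city.map.district_of.values())) >= 3:
            yb_2010 = city.population.township_year_sex.query("year == 2010")
            ba = bland_altman(
                yb_2010, city.population.census_township_year_sex, city.map.district_of
            )
            paths["bland_altman"] = out / "bland_altman.csv"
            ba.table.assign(
                mean_diff=ba.mean_diff, lower=ba.lower_limit, upper=ba.upper_limit
            ).to_csv(paths["bland_altman"], index=False)
            paths["bland_altman_flags"] = out / "bland_altman_flags.json"
            with open(paths["bland_altman_flags"], "w") as fh:
                json.dump({"flagged_districts": ba.flagged}, fh)
            manifest["bland_altman_flagged"] = ba.flagged
        else:
            log.info("fewer than 3 districts; skipping population agreement check")
        done("disaggregate")

        stage("fit")
        adj = build_adjacency(map_)
        posteriors = fit_all_strata(counts, person_years, adj, config.mcmc)
        rate_table = posterior_rate_table(posteriors)
        paths["posterior_rates"] = out / "posterior_rates.csv"
        rate_table.round(6).to_csv(paths["posterior_rates"], index=False)
        diags = {}
        if config.mcmc.n_chains >= 2:
            for key, post in posteriors.items():
                rep = check_convergence(post, n_spatial=3, seed=0)
                diags["/".join(key)] = {
                    "ok": rep.ok,
                    "flagged": rep.flagged,
                    "max_rhat": max(
                        (r for r in rep.rhat.values() if np.isfinite(r)), default=float("nan")
                    ),
                }
        paths["diagnostics"] = out / "diagnostics.json"
        with open(paths["diagnostics"], "w") as fh:
            json.dump(diags, fh, indent=2)
        done("fit")

        stage("summarize")
        standard = StandardWeights.from_person_years(person_years)
        paths.update(
            _write_summaries(out, rate_table, map_, standard, config.synthetic.age_groups)
        )
        done("summarize")
    except Exception as err:
        raise RuntimeError(f"pipeline stage {current['stage']!r} failed: {err}") from err

    manifest["timings_s"] = timings
    manifest["versions"] = _versions()
    manifest["files"] = {
        k: {"path": str(p.relative_to(out)), "sha256": _sha256(p)}
        for k, p in sorted(paths.items())
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    log.info("run complete: %s", out)
    return out


def _versions() -> dict:
    import scipy

    from . import __version__

    return {
        "amimap": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
    }


def sensitivity_rerun(config: RunConfig, district_id: str, outdir: str | Path) -> Path:
    """Re-run the pipeline without one district and compare inequality.

    Writes the excluded-district run under `<outdir>/sensitivity_<id>` and
    a side-by-side inequality comparison (one row per stratum-period)
    against the main run's table2.csv, which must already exist.
    """
    out = Path(outdir)
    main_t2 = out / "table2.csv"
    if not main_t2.exists():
        raise ConfigError("main run must be completed first (table2.csv missing)")
    sub_cfg = RunConfig(
        synthetic=config.synthetic,
        mcmc=config.mcmc,
        window_days=config.window_days,
        min_age=config.min_age,
        exclude=district_id,
        seed=config.seed,
    )
    sub_out = run_pipeline(sub_cfg, out / f"sensitivity_{district_id}")
    main = pd.read_csv(main_t2)
    sens = pd.read_csv(sub_out / "table2.csv")
    comp = main.merge(
        sens, on="characteristic", suffixes=("_main", "_excluded")
    )
    comp.to_csv(out / f"sensitivity_{district_id}_comparison.csv", index=False)
    return sub_out


def compare_inequality(
    rate_table_a: pd.DataFrame,
    rate_table_b: pd.DataFrame,
    standard: StandardWeights,
) -> pd.DataFrame:
    """Side-by-side total-rate inequality metrics from two rate tables."""
    rows = []
    for name, tab in (("a", rate_table_a), ("b", rate_table_b)):
        std = standardized_township_rates(tab, standard)
        for period, sub in std.groupby("period"):
            s = inequality_metrics(sub["rate"])
            rows.append(
                {
                    "source": name,
                    "period": period,
                    "p10": s.p10,
                    "p90": s.p90,
                    "gap": s.absolute_gap,
                    "ratio": s.relative_ratio,
                }
            )
    return pd.DataFrame(rows)
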