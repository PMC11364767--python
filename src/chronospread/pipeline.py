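"""End-to-end orchestration: simulate/ingest -> activity -> clustering ->
harmonics -> rhythm -> ratios -> day/night statistics, with CSV artifacts
and a JSON manifest for reproducibility."""

from __future__ import annotations

import json
import logging
import platform
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import activity as act
from . import clustering as clu
from . import daynight as dn
from . import harmonics as har
from . import ratios as rat
from . import rhythm as rhy
from . import stats as cstats
from .synthetic import SyntheticConfig, generate, read_posts, write_posts

log = logging.getLogger("chronospread")


@dataclass
class RunConfig:
    """Parameters of one pipeline run; defaults follow the reference
    analysis (240-post infrequent threshold, 90-minute Gaussian window
    with sigma 3 bins, 16-hour waking window, 1-hour safety margin,
    m in [1, 4] harmonics)."""

    input_path: str | None = None
    synthetic: SyntheticConfig | None = None
    infrequent_threshold: int = clu.INFREQUENT_THRESHOLD
    window_bins: int = 6
    sigma_bins: float = 3.0
    disinfo_sigma_bins: float = 6.0
    k: int = 3
    k_range: tuple = (2, 5)
    n_restarts: int = 10
    m_range: tuple = (1, 4)
    waking_hours: float = 16.0
    margin_hours: float = 1.0
    lat: float = dn.ITALY_CENTROID[0]
    lon: float = dn.ITALY_CENTROID[1]
    sun_year: int = 2020
    lockdown: tuple | None = ("2020-03-09", "2020-05-18")
    dip_draws: int = 10_000
    dip_boots: int = 2000
    run_validity: bool = True
    run_dip: bool = True
    seed: int = 0
    outdir: str | None = None


def _stage(name):
    log.info("stage: %s", name)
    return time.time()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the in-memory result bundle and, if
    ``config.outdir`` is set, writes the CSV artifacts plus manifest."""
    t0 = time.time()
    timings = {}
    results: dict = {"config": config}

    # ------------------------------------------------------------- ingest
    t = _stage("ingest")
    if config.input_path is not None:
        posts = read_posts(config.input_path)
    elif config.synthetic is not None:
        users, posts = generate(config.synthetic)
        results["planted"] = {u.user_id: u.archetype for u in users}
    else:
        raise ValueError("config needs input_path or synthetic")
    if len(posts) == 0:
        raise ValueError("no posts to analyse")
    results["posts"] = posts
    timings["ingest"] = time.time() - t

    # ----------------------------------------------------------- activity
    t = _stage("activity")
    profiles = act.bin_posts(posts)
    frequent, infrequent = clu.split_infrequent(
        profiles, config.infrequent_threshold)
    curves = {u: act.user_activity(p) for u, p in profiles.items()}
    smoothed = {u: act.smooth_circular(curves[u], config.window_bins,
                                       config.sigma_bins)
                for u in frequent}
    results.update(profiles=profiles, frequent=frequent,
                   infrequent=infrequent, user_curves=curves)
    timings["activity"] = time.time() - t

    # --------------------------------------------------------- clustering
    t = _stage("clustering")
    if len(frequent) < config.k:
        raise ValueError(
            f"only {len(frequent)} frequent users for k={config.k}")
    model = clu.fit_archetypes(smoothed, k=config.k, seed=config.seed,
                               n_restarts=config.n_restarts)
    for u in infrequent:
        model.assignments[u] = clu.INFREQUENT_ID
    if config.run_validity and len(frequent) > max(config.k_range) + 1:
        model.validity = {"table": clu.validity_scores(
            smoothed, seed=config.seed,
            k_range=range(config.k_range[0], config.k_range[1] + 1),
            n_restarts=config.n_restarts)}
    results["model"] = model
    timings["clustering"] = time.time() - t

    # ------------------------------------------- cluster curves/harmonics
    t = _stage("harmonics")
    cluster_ids = sorted({c for c in model.assignments.values()})
    coarse_activity, gauss_activity, smooth_activity, chosen_m = {}, {}, {}, {}
    for cid in cluster_ids:
        members = model.members(cid)
        if not members:
            continue
        mean_curve = act.cluster_activity(curves, members)
        pre = act.smooth_circular(mean_curve, config.window_bins,
                                  config.sigma_bins)
        m = har.select_m(pre, m_range=config.m_range)
        recon = har.reconstruct_top_m(har.dft(pre), m)
        coarse_activity[cid] = mean_curve
        gauss_activity[cid] = pre
        smooth_activity[cid] = recon
        chosen_m[cid] = m
    # name from the Gaussian-smoothed means: a low-m truncation can
    # displace a bimodal curve's peak across a naming border
    to_name = {cid: gauss_activity[cid] for cid in cluster_ids
               if cid != clu.INFREQUENT_ID}
    try:
        names = clu.name_clusters(to_name)
    except ValueError:
        if len(to_name) != 3:
            raise
        log.warning("threshold naming ambiguous; falling back to peak order")
        names = clu.name_clusters_by_rank(to_name)
    names[clu.INFREQUENT_ID] = "infrequent"
    model.names = names
    disinfo_activity = {}
    for cid in cluster_ids:
        try:
            disinfo_activity[cid] = act.disinformative_activity(
                profiles, model.members(cid),
                window_bins=config.window_bins,
                sigma_bins=config.disinfo_sigma_bins)
        except ValueError:
            disinfo_activity[cid] = None
    results.update(coarse_activity=coarse_activity,
                   gauss_activity=gauss_activity,
                   smooth_activity=smooth_activity, chosen_m=chosen_m,
                   disinfo_activity=disinfo_activity)
    timings["harmonics"] = time.time() - t

    # --------------------------------------------------------------- rhythm
    t = _stage("rhythm")
    windows, peaks = {}, {}
    for cid in cluster_ids:
        windows[cid] = rhy.heightened_onset(gauss_activity[cid],
                                            config.waking_hours)
        peaks[cid] = rhy.find_peaks(gauss_activity[cid], k=2)
    results.update(windows=windows, peaks=peaks)
    timings["rhythm"] = time.time() - t

    # --------------------------------------------------------------- ratios
    t = _stage("ratios")
    coarse_ratio, smooth_ratio, ratio_m, susceptibility = {}, {}, {}, {}
    for cid in cluster_ids:
        try:
            coarse, smooth, m, n_interp = rat.smooth_ratio(
                profiles, model.members(cid), m_range=config.m_range,
                window_bins=config.window_bins, sigma_bins=config.sigma_bins)
        except ValueError:
            continue
        coarse_ratio[cid] = coarse
        smooth_ratio[cid] = smooth
        ratio_m[cid] = m
        susceptibility[cid] = rat.susceptibility_times(smooth)
    correlations = []
    for cid in cluster_ids:
        try:
            res = rat.posts_vs_ratio_correlation(profiles, model.members(cid))
            correlations.append({"scope": names[cid], "kind": "posts_vs_ratio",
                                 "rho": res.statistic, "p": res.p})
        except ValueError:
            pass
        if cid in coarse_ratio:
            for label, ratio_curve in (("coarse", coarse_ratio[cid]),
                                       ("smooth", smooth_ratio[cid])):
                base = coarse_activity[cid] if label == "coarse" \
                    else smooth_activity[cid]
                res = rat.activity_ratio_correlation(base, ratio_curve)
                correlations.append({"scope": names[cid],
                                     "kind": f"activity_vs_ratio_{label}",
                                     "rho": res.statistic, "p": res.p})
    res = rat.posts_vs_ratio_correlation(profiles)
    correlations.append({"scope": "total", "kind": "posts_vs_ratio",
                         "rho": res.statistic, "p": res.p})
    results.update(coarse_ratio=coarse_ratio, smooth_ratio=smooth_ratio,
                   ratio_m=ratio_m, susceptibility=susceptibility,
                   correlations=pd.DataFrame(correlations))
    timings["ratios"] = time.time() - t

    # ------------------------------------------------------------- daynight
    t = _stage("daynight")
    borders = dn.clock_day_borders(config.lat, config.lon, config.sun_year)
    parts = {
        "clock": dn.partition("clock", config.margin_hours, borders=borders),
        "daylight": dn.partition("daylight", config.margin_hours,
                                 lat=config.lat, lon=config.lon,
                                 year=config.sun_year),
    }
    dn_rows = []
    for cid in coarse_ratio:
        parts_c = dict(parts)
        parts_c["waking"] = dn.partition("waking", config.margin_hours,
                                         window=windows[cid])
        for defname, part in parts_c.items():
            try:
                if defname == "daylight":
                    # pool monthly labels: test each month's labelling of
                    # the same ratio curve, merged into one day/night split
                    res = _daylight_test(coarse_ratio[cid].values, part)
                else:
                    res = dn.day_night_test(coarse_ratio[cid].values, part)
                dn_rows.append({"cluster": names[cid], "definition": defname,
                                "U": res.statistic, "p": res.p,
                                "sided": res.sided,
                                "less": res.smaller or ""})
            except ValueError as exc:
                log.warning("day/night %s %s: %s", names[cid], defname, exc)
    comparisons = []
    ordered = [cid for cid in cluster_ids if cid in coarse_ratio]
    for kind, curves_by_c in (("coarse", coarse_ratio), ("smooth", smooth_ratio)):
        for i, ca in enumerate(ordered):
            for cb in ordered[i + 1:]:
                res = dn.cluster_ratio_comparison(
                    curves_by_c[ca].values, curves_by_c[cb].values, "less")
                comparisons.append({"kind": kind, "row": names[ca],
                                    "col": names[cb], "U": res.statistic,
                                    "p": res.p})
    results.update(borders=borders, daynight=pd.DataFrame(dn_rows),
                   comparisons=pd.DataFrame(comparisons))
    if config.lockdown is not None:
        try:
            results["lockdown"] = dn.lockdown_compare(
                posts, model.assignments, config.lockdown, names)
            results["lockdown_chi2"] = dn.lockdown_chi_square(
                posts, model.assignments, config.lockdown)
        except (ValueError, KeyError) as exc:
            log.warning("lockdown comparison skipped: %s", exc)
    timings["daynight"] = time.time() - t

    # ----------------------------------------------------------------- stats
    t = _stage("stats")
    stat_rows = []
    if config.run_dip:
        for cid in cluster_ids:
            res = cstats.dip_test_curve(
                act.BIN_STARTS, np.maximum(smooth_activity[cid].values, 0),
                n_draws=config.dip_draws, n_boot=config.dip_boots,
                seed=config.seed)
            stat_rows.append({"cluster": names[cid], "test": "dip",
                              "statistic": res.statistic, "p": res.p})
    for cid in cluster_ids:
        res = cstats.shapiro_wilk(coarse_activity[cid].values)
        stat_rows.append({"cluster": names[cid], "test": "shapiro_activity",
                          "statistic": res.statistic, "p": res.p})
    results["stat_tests"] = pd.DataFrame(stat_rows)
    timings["stats"] = time.time() - t

    results["timings"] = timings
    log.info("pipeline done in %.1f s", time.time() - t0)
    if config.outdir is not None:
        write_artifacts(results, Path(config.outdir))
    return results


def _daylight_test(ratio_values, part) -> cstats.StatResult:
    """Day/night test under the monthly daylight labelling, pooling the
    per-month day and night bin samples."""
    day, night = [], []
    for month in range(1, 13):
        day.extend(ratio_values[part.bins("day", month)])
        night.extend(ratio_values[part.bins("night", month)])
    day = np.asarray([v for v in day if np.isfinite(v)])
    night = np.asarray([v for v in night if np.isfinite(v)])
    if day.size == 0 or night.size == 0:
        raise ValueError("empty day or night sample")
    two = cstats.mann_whitney(day, night, "two-sided")
    if two.p < 0.05:
        direction = "less" if two.statistic < day.size * night.size / 2 \
            else "greater"
        res = cstats.mann_whitney(day, night, direction)
        res.smaller = "day" if direction == "less" else "night"
        return res
    return two


# ---------------------------------------------------------------------------
# Artifacts
# ---------------------------------------------------------------------------

def _curve_frame(curves: dict, names: dict) -> pd.DataFrame:
    rows = []
    for cid, curve in curves.items():
        if curve is None:
            continue
        values = curve.values if hasattr(curve, "values") else curve
        for t, v in zip(act.BIN_STARTS, values):
            rows.append({"cluster": names.get(cid, str(cid)),
                         "bin_start_hour": t, "value": v})
    return pd.DataFrame(rows)


def write_artifacts(results: dict, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config: RunConfig = results["config"]
    model = results["model"]
    names = model.names
    write_posts(results["posts"], outdir / "posts.csv")
    model.to_frame().to_csv(outdir / "assignments.csv", index=False)
    if model.validity:
        model.validity["table"].to_csv(outdir / "validity.csv", index=False)
    for key, fname in (("coarse_activity", "cluster_activity_coarse.csv"),
                       ("smooth_activity", "cluster_activity_smooth.csv"),
                       ("disinfo_activity", "disinfo_activity.csv"),
                       ("coarse_ratio", "ratio_coarse.csv"),
                       ("smooth_ratio", "ratio_smooth.csv")):
        _curve_frame(results[key], names).to_csv(outdir / fname, index=False)
    wrows = [{"cluster": names[cid], "onset": w.onset, "end": w.end,
              "n": w.n} for cid, w in results["windows"].items()]
    pd.DataFrame(wrows).to_csv(outdir / "windows.csv", index=False)
    prows = [{"cluster": names[cid], "rank": i + 1, "hour": h, "value": v}
             for cid, ps in results["peaks"].items()
             for i, (h, v) in enumerate(ps)]
    pd.DataFrame(prows).to_csv(outdir / "peaks.csv", index=False)
    srows = [{"cluster": names[cid], "bin": int(b),
              "hour": float(act.BIN_STARTS[b])}
             for cid, bins in results["susceptibility"].items() for b in bins]
    pd.DataFrame(srows).to_csv(outdir / "susceptibility.csv", index=False)
    results["correlations"].to_csv(outdir / "correlations.csv", index=False)
    results["daynight"].to_csv(outdir / "daynight_tests.csv", index=False)
    results["comparisons"].to_csv(outdir / "cluster_comparisons.csv",
                                  index=False)
    if "lockdown" in results:
        results["lockdown"].to_csv(outdir / "lockdown.csv", index=False)
    results["stat_tests"].to_csv(outdir / "stat_tests.csv", index=False)
    manifest = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "parameters": {
            k: v for k, v in asdict(config).items()
            if k not in ("synthetic", "outdir", "input_path")
            and not isinstance(v, (dict,))
        },
        "synthetic": (config.synthetic.to_yaml()
                      if config.synthetic is not None else None),
        "clock_borders": list(results["borders"]),
        "chosen_m_activity": {str(names[c]): int(m)
                              for c, m in results["chosen_m"].items()},
        "chosen_m_ratio": {str(names[c]): int(m)
                           for c, m in results["ratio_m"].items()},
        "n_users": len(results["profiles"]),
        "n_posts": int(len(results["posts"])),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
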