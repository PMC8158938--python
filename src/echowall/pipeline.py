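"""End-to-end orchestration: simulate -> auralize -> SNQ -> listeners -> stats.

The pipeline is a library function (``run_pipeline``) driven by a fully
serializable :class:`PipelineConfig`; every artifact lands in the output
directory and a manifest records the configuration hash and file
checksums, so identical configurations reproduce identical outputs.
Two scale presets exist: ``test`` (coarse 10 mm grid, 48 kHz output,
seconds per impulse response) and ``paper`` (1.3 mm grid, 192 kHz
output; hours — intended for offline reproduction runs only).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import abx_stats, annpredict, auralize, click, fdtd, features, geometry, synthetic_data

SCALE_PRESETS = {
    "test": {"spacing": 0.010, "margin": 0.30, "output_rate": 48_000.0},
    "paper": {"spacing": 0.0013, "margin": 1.0, "output_rate": 192_000.0},
}


@dataclass
class PipelineConfig:
    textures: list[str] = field(default_factory=lambda: ["flat", "circular_convex", "aperture"])
    distances: list[float] = field(default_factory=lambda: [0.81])
    configurations: list[str] = field(default_factory=lambda: list(auralize.CONFIGURATIONS))
    scale: str = "test"
    sound_speed: float = 342.0
    seed: int = 0
    loudness_metric: str = "a_weighted_exposure"
    full_scale_spl: float = 94.0
    target_sel: float = 51.0
    texture_overrides: dict = field(default_factory=dict)
    outdir: str = "pipeline_out"
    n_participants: int = 14
    n_reps: int = 3

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True, default=str).encode()).hexdigest()[:16]


def _window_for(distance: float) -> float:
    return fdtd.WINDOW_NEAR if distance < 2.5 else fdtd.WINDOW_FAR


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in dependency order and return the manifest.

    Stages whose outputs already exist under a matching configuration
    hash are skipped, making re-runs idempotent.  On a stage failure the
    partial manifest written so far is preserved on disk.
    """
    preset = SCALE_PRESETS[config.scale]
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest: dict = {"config": asdict(config), "config_hash": config.config_hash(), "stages": {}, "files": {}}
    previous = None
    if manifest_path.exists():
        previous = json.loads(manifest_path.read_text())
        if previous.get("config_hash") != manifest["config_hash"]:
            previous = None

    def _up_to_date(stage: str, paths: list[Path]) -> bool:
        return previous is not None and stage in previous.get("stages", {}) and all(p.exists() for p in paths)

    def _record(stage: str, paths: list[Path]) -> None:
        manifest["stages"][stage] = [str(p.relative_to(out)) for p in paths]
        for p in paths:
            manifest["files"][str(p.relative_to(out))] = _sha256(p)
        manifest_path.write_text(json.dumps(manifest, indent=2))

    sim_config = fdtd.SimulationConfig(sound_speed=config.sound_speed, output_rate=preset["output_rate"])
    calibration = auralize.Calibration(full_scale_spl=config.full_scale_spl, target_sel=config.target_sel)
    metric = auralize.METRICS[config.loudness_metric]()

    try:
        # --- stage: RIR simulation -------------------------------------
        rir_dir = out / "rir"
        rir_dir.mkdir(exist_ok=True)
        rir_paths = [rir_dir / f"{t}_{d:g}.wav" for t in config.textures for d in config.distances]
        if not _up_to_date("simulate", rir_paths):
            for d in config.distances:
                window = _window_for(d)
                duration = window + 2e-3
                for t in config.textures:
                    spec = geometry.make_texture(t, d, config.texture_overrides.get(t))
                    scene = geometry.rasterize(spec, spacing=preset["spacing"], margin=preset["margin"])
                    wall = fdtd.run_fdtd(scene, sim_config, duration)
                    free = fdtd.run_fdtd(scene.without_solids(), sim_config, duration)
                    bundle = fdtd.split_components(wall, free, window, texture=t, distance=d)
                    bundle.save(rir_dir / f"{t}_{d:g}.wav")
        _record("simulate", rir_paths)

        # --- stage: click ----------------------------------------------
        click_path = out / "click.wav"
        the_click = click.generate_click()
        if not _up_to_date("click", [click_path]):
            the_click.save(click_path)
        _record("click", [click_path])

        # --- stage: auralization ---------------------------------------
        filters = synthetic_data.make_fixture_filters(seed=config.seed)
        stim_dir = out / "stimuli"
        stim_dir.mkdir(exist_ok=True)
        stimulus_sets: dict[tuple[float, str], dict[str, auralize.Stimulus]] = {}
        stim_paths = []
        for d in config.distances:
            obrirs = {
                t: auralize.assemble_obrir(fdtd.RIRBundle.load(rir_dir / f"{t}_{d:g}.wav"), filters)
                for t in config.textures
            }
            reference = np.convolve(next(iter(obrirs.values())).direct[0], the_click.samples)
            gain = auralize.session_gain(reference, the_click.rate, calibration)
            for mode in config.configurations:
                configured = {t: auralize.apply_configuration(o, mode) for t, o in obrirs.items()}
                extra = {t: 1.0 for t in configured}
                if mode == "reflections_only":
                    echoes = [np.convolve(o.left, the_click.samples) for o in configured.values()]
                    gains = auralize.equalize_set(echoes, the_click.rate, metric=metric)
                    normals = {
                        t: auralize.auralize_stimulus(auralize.apply_configuration(obrirs[t], "normal"), the_click, calibration, gain)
                        for t in configured
                    }
                    for (t, o), g in zip(configured.items(), gains):
                        eq = np.convolve(o.left, the_click.samples) * g
                        extra[t] = g * auralize.level_match_gain(eq, normals[t].left)
                stims = {
                    t: auralize.auralize_stimulus(o, the_click, calibration, gain, extra_gain=extra[t])
                    for t, o in configured.items()
                }
                stimulus_sets[(d, mode)] = stims
                for t, s in stims.items():
                    p = stim_dir / f"{t}_{d:g}_{mode}.wav"
                    s.save(p)
                    stim_paths.append(p)
        _record("auralize", stim_paths)

        # --- stage: SNQ features ---------------------------------------
        snq_path = out / "snq.csv"
        snq = features.snq_tables(stimulus_sets, rate=the_click.rate, n_textures=len(config.textures))
        snq.to_csv(snq_path, index=False)
        _record("snq", [snq_path])

        # --- stage: synthetic listeners --------------------------------
        responses_path = out / "responses.csv"
        listener = synthetic_data.ListenerModel(seed=config.seed)
        trials = synthetic_data.simulate_experiment(
            listener, snq, n_participants=config.n_participants, n_reps=config.n_reps
        )
        trials.to_csv(responses_path, index=False)
        _record("listeners", [responses_path])

        # --- stage: statistics -----------------------------------------
        scored = abx_stats.score_trials(trials)
        dfs = abx_stats.compute_df(scored, ["configuration", "distance", "pair_i", "pair_j"])
        dfs_path = out / "df.csv"
        dfs.to_csv(dfs_path, index=False)
        stats_paths = [dfs_path]
        if len(config.distances) >= 2 and len(config.configurations) >= 2 and len(config.textures) >= 2:
            pairwise = synthetic_data.pairwise_df_table(scored)
            anova = abx_stats.anova_from_pairwise(pairwise)
            anova_path = out / "anova.csv"
            anova.table.to_csv(anova_path, index=False)
            (out / "anova.txt").write_text(anova.report() + "\n")
            stats_paths += [anova_path, out / "anova.txt"]
        _record("stats", stats_paths)

        # --- stage: ANN ------------------------------------------------
        block = next(iter(stimulus_sets))
        snq_block = snq[(snq["distance"] == block[0]) & (snq["configuration"] == block[1])]
        ordered = ordered_pair_df(scored, distance=block[0], configuration=block[1])
        dataset = annpredict.PairDataset.from_tables(snq_block, ordered)
        model, trace, summary = annpredict.train_restarts(dataset, seeds=range(config.seed, config.seed + 5))
        ann_path = out / "ann.json"
        model.save(ann_path)
        (out / "ann_summary.csv").write_text(summary.to_csv(index=False))
        _record("ann", [ann_path, out / "ann_summary.csv"])
    except Exception as err:  # preserve partial manifest with the failing stage named
        done = list(manifest["stages"])
        manifest["failed_after"] = done
        manifest["error"] = str(err)
        manifest_path.write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline failed after stages {done}: {err}") from err

    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest


def ordered_pair_df(scored: pd.DataFrame, distance: float, configuration: str) -> pd.DataFrame:
    """Ordered-pair DF table for the ANN split.

    The ABX design does not distinguish (i, j) from (j, i); trials are
    assigned to the two orders by their X assignment (X = A -> (i, j),
    X = B -> (j, i)), giving two disjoint DF estimates per pair with
    independent response noise, as the reversed-pair test set requires.
    """
    sel = scored[(scored["distance"] == distance) & (scored["configuration"] == configuration)]
    rows = []
    for (i, j), grp in sel.groupby(["pair_i", "pair_j"], observed=True):
        fwd = grp[grp["x_assignment"] == "A"]
        rev = grp[grp["x_assignment"] == "B"]
        if len(fwd) == 0 or len(rev) == 0:
            raise ValueError(f"pair {(i, j)} lacks trials in one order")
        rows.append({"pair_i": i, "pair_j": j, "df": fwd["correct"].mean()})
        rows.append({"pair_i": j, "pair_j": i, "df": rev["correct"].mean()})
    return pd.DataFrame(rows)
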