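"""End-to-end in-silico experiment: generate → select → segment → evaluate → test.

Mirrors the in-vivo design — by default 8 animals × 4 injections
(three polymer-shelled doses and a SonoVue-like reference) × 3 observers —
on synthetic phantoms. One global seed fans out to per-(stage, dose, animal,
observer) child seeds through :class:`numpy.random.SeedSequence` spawn keys,
so any subset of the run reproduces independently of execution order:

    SeedSequence(entropy=seed, spawn_key=(stage, dose_index, animal, observer))

with stage 0 = phantom rendering, 1 = observer landmarks, 2 = score tables,
3 = physiological logs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import evaluation, frame_selection, reference, scoring, stats
from .evaluation import DelineationRecord
from .phantom import (
    IN_VIVO_SCORE_PROBS,
    PhantomConfig,
    generate_sequence,
    simulate_physio_log,
    simulate_score_table,
)
from .segmentation import SegmentationSpec, segment

DEFAULT_DOSES = ("sonovue-1.5", "1.5", "3", "5")
REFERENCE_DOSE = "sonovue-1.5"


@dataclass(frozen=True)
class RunConfig:
    n_animals: int = 8
    n_observers: int = 3
    doses: tuple = DEFAULT_DOSES
    seed: int = 0
    image_size: int = 256
    n_iterations: int = 2500
    landmark_jitter_sd: float = 1.5
    min_score: float = 0.25
    phantom_overrides: dict = field(default_factory=dict)
    segmentation_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.doses)) != len(self.doses):
            raise ValueError("dose labels must be unique")

    @classmethod
    def reduced(cls, **overrides) -> "RunConfig":
        """Down-scaled preset (128 px rasters, 800 iterations) for fast runs."""
        params = dict(image_size=128, n_iterations=800)
        params.update(overrides)
        return cls(**params)


@dataclass
class ExperimentResult:
    config: RunConfig
    delineations: pd.DataFrame
    dice_bins: pd.DataFrame
    score_table: scoring.SegmentScoreTable
    durations: pd.DataFrame
    physio: stats.PhysioLog
    score_tests: pd.DataFrame
    dice_tests: pd.DataFrame
    physio_summary: pd.DataFrame
    manifest: dict


def _child_seed(seed: int, *key: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=seed, spawn_key=tuple(key))


def _segment_one(frame, truth, av_plane, config: RunConfig):
    r, c = ndimage.center_of_mass(truth)
    spec = SegmentationSpec(
        seed_center=(r, c),
        expected_area=float(truth.sum()),
        av_plane=av_plane,
        n_iterations=config.n_iterations,
        **config.segmentation_overrides,
    )
    return segment(frame, spec)


def run_experiment(config: RunConfig) -> ExperimentResult:
    """Run the full in-silico study for one configuration.

    Per (dose, animal): render a phantom injection sequence, select the
    best-enhanced frame, segment it with the AV-constrained geodesic active
    contour, and compare against one jittered 20-landmark spline reference
    per observer. Per dose: simulated observer score tables and
    useful-duration labels. Globally: physiological logs and the full
    statistics battery against the reference dose.
    """
    records: list[DelineationRecord] = []
    durations = []
    for d_idx, dose in enumerate(config.doses):
        for animal in range(1, config.n_animals + 1):
            ph_seed = int(_child_seed(config.seed, 0, d_idx, animal).generate_state(1)[0])
            ph_cfg = PhantomConfig.for_dose(
                dose,
                rng_seed=ph_seed,
                image_height=config.image_size,
                image_width=config.image_size,
                **config.phantom_overrides,
            )
            seq = generate_sequence(ph_cfg)
            truth = seq.truth_mask
            selections = frame_selection.select_frames(seq, truth)
            durations.append(
                {
                    "dose": dose,
                    "animal": animal,
                    "label": frame_selection.useful_duration(
                        selections, config.min_score
                    ),
                }
            )
            best = max(selections, key=lambda s: s.enhancement_score)
            mask = _segment_one(
                seq.frames[best.selected_frame], truth, seq.av_plane, config
            )
            for observer in range(1, config.n_observers + 1):
                rng = np.random.default_rng(
                    _child_seed(config.seed, 1, d_idx, animal, observer)
                )
                lm = reference.sample_landmarks(
                    truth, jitter_sd=config.landmark_jitter_sd, rng=rng
                )
                ref_mask = reference.landmarks_to_mask(lm, truth.shape)
                records.append(
                    DelineationRecord(
                        animal=animal,
                        observer=observer,
                        dose_label=dose,
                        dice=evaluation.dice(mask, ref_mask),
                    )
                )

    dose_probs = {d: IN_VIVO_SCORE_PROBS[d] for d in config.doses if d in IN_VIVO_SCORE_PROBS}
    score_table = simulate_score_table(
        config.n_animals,
        config.n_observers,
        dose_probs or None,
        rng=np.random.default_rng(_child_seed(config.seed, 2)),
    ) if config.doses else scoring.SegmentScoreTable(
        pd.DataFrame(columns=scoring.COLUMNS)
    )

    injections = [(dose, 10 * (i + 1)) for i, dose in enumerate(config.doses)]
    physio = simulate_physio_log(
        config.n_animals,
        injections,
        rng=np.random.default_rng(_child_seed(config.seed, 3)),
    )

    delineations = evaluation.records_to_frame(records)
    dice_bins = (
        evaluation.tabulate(records) if records else pd.DataFrame(columns=["dose"])
    )
    score_tests = _score_tests(score_table, config)
    dice_tests = _dice_tests(delineations, config)
    physio_summary = _physio_summary(physio, config)

    manifest = {
        "config": dataclasses.asdict(config),
        "seed_scheme": "SeedSequence(entropy=seed, spawn_key=(stage, dose_index, animal, observer))",
        "n_delineations": len(delineations),
        "n_score_records": len(score_table),
    }
    return ExperimentResult(
        config=config,
        delineations=delineations,
        dice_bins=dice_bins,
        score_table=score_table,
        durations=pd.DataFrame(durations),
        physio=physio,
        score_tests=score_tests,
        dice_tests=dice_tests,
        physio_summary=physio_summary,
        manifest=manifest,
    )


def _score_tests(table: scoring.SegmentScoreTable, config: RunConfig) -> pd.DataFrame:
    """Signed-rank comparisons of each dose against the reference dose,
    overall and per region."""
    rows = []
    if REFERENCE_DOSE not in config.doses or len(table) == 0:
        return pd.DataFrame(rows)
    for dose in config.doses:
        if dose == REFERENCE_DOSE:
            continue
        for region in ("all",) + scoring.REGIONS:
            pairs = scoring.paired_scores(
                table,
                dose,
                REFERENCE_DOSE,
                region=None if region == "all" else region,
            )
            res = stats.wilcoxon_signed_rank(pairs)
            rows.append(
                {
                    "dose": dose,
                    "region": region,
                    "n_pairs": len(pairs),
                    "statistic": res.statistic,
                    "p": res.p_value,
                    "band": stats.significance_band(res.p_value),
                }
            )
    return pd.DataFrame(rows)


def _dice_tests(delineations: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """McNemar one-vs-rest tests per Dice bin, each dose vs the reference."""
    rows = []
    if REFERENCE_DOSE not in config.doses or len(delineations) == 0:
        return pd.DataFrame(rows)
    key = ["animal", "observer"]
    ref = delineations[delineations["dose"] == REFERENCE_DOSE].set_index(key)["bin"]
    for dose in config.doses:
        if dose == REFERENCE_DOSE:
            continue
        cur = delineations[delineations["dose"] == dose].set_index(key)["bin"]
        cur = cur.reindex(ref.index)
        for target_bin in evaluation.DICE_BINS:
            pairs = list(
                zip(
                    stats.bin_indicators(cur.tolist(), target_bin),
                    stats.bin_indicators(ref.tolist(), target_bin),
                )
            )
            res = stats.mcnemar(pairs)
            rows.append(
                {
                    "dose": dose,
                    "bin": target_bin,
                    "n_discordant": res.n_effective,
                    "p": res.p_value,
                    "band": stats.significance_band(res.p_value),
                }
            )
    return pd.DataFrame(rows)


def _physio_summary(physio: stats.PhysioLog, config: RunConfig) -> pd.DataFrame:
    """Mean ± sd relative difference (%) around each injection, with the
    paired-t p-value (needs ≥2 animals for a test)."""
    rows = []
    for dose in config.doses:
        eff = stats.physio_effect(physio, dose)
        for var in stats.PHYSIO_VARIABLES:
            diffs = eff[eff["variable"] == var]["rel_diff_pct"].to_numpy()
            row = {
                "dose": dose,
                "variable": var,
                "mean_pct": float(diffs.mean()),
                "sd_pct": float(diffs.std(ddof=1)) if len(diffs) > 1 else 0.0,
            }
            if len(diffs) >= 2 and np.std(diffs) > 0:
                res = stats.paired_t(diffs)
                row["p"] = res.p_value
                row["band"] = stats.significance_band(res.p_value)
            else:
                row["p"] = np.nan
                row["band"] = "NS"
            rows.append(row)
    return pd.DataFrame(rows)


def report(result: ExperimentResult) -> dict[str, pd.DataFrame]:
    """Summary tables: score distributions (with significance bands),
    useful-duration labels, Dice-bin counts, physiology percentages."""
    tables = {}
    if len(result.score_table):
        tables["score_distribution"] = scoring.distribution_table(result.score_table)
    else:
        tables["score_distribution"] = pd.DataFrame()
    if len(result.durations):
        dur = (
            result.durations.groupby("dose")["label"]
            .agg(lambda s: s.mode().iloc[0])
            .reset_index()
            .rename(columns={"label": "useful_period"})
        )
    else:
        dur = pd.DataFrame(columns=["dose", "useful_period"])
    tables["useful_duration"] = dur
    tables["dice_bins"] = result.dice_bins
    tables["score_tests"] = result.score_tests
    tables["dice_tests"] = result.dice_tests
    tables["physio"] = result.physio_summary
    return tables


def write_result(result: ExperimentResult, outdir) -> Path:
    """Write all result tables, the raw records and the manifest to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.delineations.to_csv(outdir / "delineations.csv", index=False)
    result.score_table.to_csv(outdir / "segment_scores.csv")
    result.durations.to_csv(outdir / "useful_durations.csv", index=False)
    result.physio.to_csv(outdir / "physio_log.csv")
    for name, table in report(result).items():
        table.to_csv(outdir / f"{name}.csv", index=False)
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(result.manifest, indent=2, default=str))
    return manifest_path
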