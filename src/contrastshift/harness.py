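"""Experimental design: splits, cross-validation, the four augmentation
conditions, in-/out-of-distribution evaluation, and paired statistics.

In-distribution data are contrast-domain phantoms with labels; the
out-of-distribution set consists of non-contrast phantoms never seen in
training. Models are trained per condition on identical case splits and
identical cached spatial-augmentation streams (only the intensity branch
differs), so between-condition differences are attributable to the
augmentation method. Each fold's model also evaluates the *complete*
out-of-distribution set, and the out-of-distribution summary SD is taken
across folds.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import augment as aug
from . import ct_io, metrics, phantom
from .cyclegan import CycleGANTranslator
from .grids import HU, LabelVolume, VolumeGrid
from .phantom import PhantomCase
from .stats import ComparisonResult, wilcoxon_signed_rank
from .unet import UNet3DSegmenter


# ---------------------------------------------------------------------------
# Splits


@dataclass
class SplitPlan:
    fold_id: int
    train_ids: list[str]
    val_ids: list[str]
    test_ids: list[str]
    ratios: tuple[float, float, float] = (0.75, 0.05, 0.20)

    def assert_disjoint(self) -> None:
        sets = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        for i in range(3):
            for j in range(i + 1, 3):
                if sets[i] & sets[j]:
                    raise AssertionError(f"split leakage in fold {self.fold_id}: {sets[i] & sets[j]}")


def largest_remainder_sizes(n: int, ratios: tuple[float, ...]) -> tuple[int, ...]:
    """Integer allocation of n by ratios, preserving the total."""
    quotas = [n * r for r in ratios]
    sizes = [int(np.floor(q)) for q in quotas]
    remainder = n - sum(sizes)
    order = sorted(range(len(ratios)), key=lambda i: (-(quotas[i] - sizes[i]), i))
    for i in order[:remainder]:
        sizes[i] += 1
    return tuple(sizes)


def make_split(case_ids: list[str], ratios=(0.75, 0.05, 0.20), seed: int = 0,
               fold_id: int = 0) -> SplitPlan:
    if len(case_ids) < 5:
        raise ValueError("need >= 5 cases to split")
    sizes = largest_remainder_sizes(len(case_ids), ratios)
    if any(s == 0 for s in sizes):
        raise ValueError(f"split {sizes} leaves an empty partition for n={len(case_ids)}")
    rng = np.random.default_rng(seed)
    order = [case_ids[i] for i in rng.permutation(len(case_ids))]
    plan = SplitPlan(
        fold_id=fold_id,
        train_ids=order[: sizes[0]],
        val_ids=order[sizes[0]: sizes[0] + sizes[1]],
        test_ids=order[sizes[0] + sizes[1]:],
        ratios=tuple(ratios),
    )
    plan.assert_disjoint()
    return plan


def make_cv_folds(case_ids: list[str], k: int = 5, seed: int = 0,
                  ratios=(0.75, 0.05, 0.20)) -> list[SplitPlan]:
    """k folds with rotating test blocks; every case tested exactly once."""
    n = len(case_ids)
    if k > n:
        raise ValueError(f"k={k} folds but only {n} cases")
    rng = np.random.default_rng(seed)
    order = [case_ids[i] for i in rng.permutation(n)]
    blocks = [list(b) for b in np.array_split(np.array(order, dtype=object), k)]
    train_val_ratio = (ratios[0] / (ratios[0] + ratios[1]), ratios[1] / (ratios[0] + ratios[1]))
    plans = []
    for fold in range(k):
        test = blocks[fold]
        rest = [cid for b, block in enumerate(blocks) if b != fold for cid in block]
        n_train, n_val = largest_remainder_sizes(len(rest), train_val_ratio)
        if n_val == 0:
            n_train -= 1
            n_val = 1
        plan = SplitPlan(fold_id=fold, train_ids=rest[:n_train],
                         val_ids=rest[n_train:], test_ids=test, ratios=tuple(ratios))
        plan.assert_disjoint()
        plans.append(plan)
    return plans


# ---------------------------------------------------------------------------
# Training per condition


@dataclass
class StoppingPolicy:
    max_iterations: int = 10000
    patience_epochs: int = 10
    selection: str = "best_validation"

    def __post_init__(self) -> None:
        if self.patience_epochs < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class EvalRecord:
    case_id: str
    condition: str
    domain: str  # in_distribution | out_of_distribution
    fold_id: int
    dice: float
    vol_error: float


def _clipped(volume: VolumeGrid) -> VolumeGrid:
    return ct_io.clip_hu(volume)


def build_condition_caches(
    cases: list[PhantomCase],
    condition: str,
    augment_config: aug.AugmentConfig,
    organ: str,
    translated: dict[str, VolumeGrid] | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Normalized (image, mask) training pairs: all cached variants of all cases."""
    pairs = []
    for case in cases:
        image = _clipped(case.contrast_volume)
        mask = case.masks[organ]
        trans = None
        if condition == "cyclegan":
            if translated is None or case.case_id not in translated:
                raise ValueError(f"no translated volume for case {case.case_id}")
            trans = _clipped(translated[case.case_id])
        variants = aug.cache_variants(image, mask, condition, augment_config,
                                      case.case_id, translated_volume=trans)
        for var in variants:
            normalized = ct_io.normalize_zmuv(var.image)
            pairs.append((normalized.values.astype(np.float32),
                          var.mask.values.astype(np.float32)))
    return pairs


def train_segmenter(
    train_cases: list[PhantomCase],
    val_cases: list[PhantomCase],
    condition: str,
    augment_config: aug.AugmentConfig,
    organ: str,
    policy: StoppingPolicy,
    unet_params: dict,
    translated: dict[str, VolumeGrid] | None = None,
    seed: int = 0,
) -> UNet3DSegmenter:
    """Train one condition's model with best-validation checkpoint selection."""
    if not val_cases:
        raise ValueError("empty validation set: checkpoint selection undefined")
    pairs = build_condition_caches(train_cases, condition, augment_config, organ, translated)
    val_pairs = [
        (ct_io.preprocess(c.contrast_volume).values.astype(np.float32),
         c.masks[organ].values.astype(np.float32))
        for c in val_cases
    ]

    def sample_fn(rng):
        return pairs[rng.integers(len(pairs))]

    est = UNet3DSegmenter(
        max_iterations=policy.max_iterations,
        patience_epochs=policy.patience_epochs,
        seed=seed,
        **unet_params,
    )
    est.fit_sampler(sample_fn, val_pairs, n_train_samples=len(pairs))
    return est


def evaluate_fold(
    model: UNet3DSegmenter,
    in_dist_cases: list[PhantomCase],
    out_dist_cases: list[PhantomCase],
    organ: str,
    condition: str,
    fold_id: int,
) -> list[EvalRecord]:
    records = []
    for domain, cases, volume_of in (
        ("in_distribution", in_dist_cases, lambda c: c.contrast_volume),
        ("out_of_distribution", out_dist_cases, lambda c: c.noncontrast_volume),
    ):
        for case in cases:
            if organ not in case.masks:
                warnings.warn(f"case {case.case_id}: missing ground truth for {organ!r}; skipped")
                continue
            pred = model.predict(ct_io.preprocess(volume_of(case)), case_id=case.case_id)
            truth = case.masks[organ]
            records.append(EvalRecord(
                case_id=case.case_id,
                condition=condition,
                domain=domain,
                fold_id=fold_id,
                dice=metrics.dice_score_empty_as_zero(truth, pred.mask),
                vol_error=metrics.volume_error(truth, pred.mask,
                                               volume_of(case).spacing_mm),
            ))
    return records


# ---------------------------------------------------------------------------
# Reporting


def build_report(records: list[EvalRecord]) -> pd.DataFrame:
    """Condition x domain summary: mean +/- SD over folds of fold-mean metrics."""
    if not records:
        raise ValueError("no evaluation records")
    df = pd.DataFrame([asdict(r) for r in records])
    fold_means = (
        df.groupby(["condition", "domain", "fold_id"])[["dice", "vol_error"]]
        .mean()
        .reset_index()
    )
    summary = (
        fold_means.groupby(["condition", "domain"])
        .agg(
            dice_mean=("dice", "mean"), dice_sd=("dice", "std"),
            vol_error_mean=("vol_error", "mean"), vol_error_sd=("vol_error", "std"),
            n_folds=("fold_id", "count"),
        )
        .reset_index()
        .sort_values(["domain", "condition"], kind="stable")
        .reset_index(drop=True)
    )
    best = summary.groupby("domain")["dice_mean"].transform("max")
    summary["best_dice_in_domain"] = summary["dice_mean"] == best
    return summary


def report_markdown(summary: pd.DataFrame) -> str:
    lines = [
        "| condition | domain | Dice (mean ± SD) | volume error (mean ± SD) |",
        "|---|---|---|---|",
    ]
    for _, row in summary.iterrows():
        dice = f"{row.dice_mean:.3f} ± {row.dice_sd:.3f}" if np.isfinite(row.dice_sd) \
            else f"{row.dice_mean:.3f} ± n/a"
        ve = f"{row.vol_error_mean:.3f} ± {row.vol_error_sd:.3f}" if np.isfinite(row.vol_error_sd) \
            else f"{row.vol_error_mean:.3f} ± n/a"
        star = " *" if row.best_dice_in_domain else ""
        lines.append(f"| {row.condition}{star} | {row.domain} | {dice} | {ve} |")
    return "\n".join(lines)


def paired_condition_comparison(records: list[EvalRecord], condition_a: str,
                                condition_b: str, domain: str,
                                metric: str = "dice") -> ComparisonResult:
    df = pd.DataFrame([asdict(r) for r in records])
    df = df[df.domain == domain]
    a = df[df.condition == condition_a].set_index(["case_id", "fold_id"])[metric]
    b = df[df.condition == condition_b].set_index(["case_id", "fold_id"])[metric]
    common = a.index.intersection(b.index)
    return wilcoxon_signed_rank(a.loc[common].to_numpy(), b.loc[common].to_numpy(),
                                condition_a, condition_b)


# ---------------------------------------------------------------------------
# Full experiment


@dataclass
class ExperimentConfig:
    grid: int = 32
    n_cases: int = 40
    n_ood: int = 10
    n_translator_cases: int = 24
    n_labeled_classifier: int = 12  # per class, for the contrast classifier
    noise_sd_hu: float = 10.0
    organ: str = "kidney"
    conditions: tuple[str, ...] = ("standard", "cyclegan")
    k_folds: int = 2
    seed: int = 0
    translator_params: dict = field(default_factory=dict)
    unet_params: dict = field(default_factory=dict)
    augment_params: dict = field(default_factory=dict)
    max_iterations: int = 480
    patience_epochs: int = 10

    def phantom_config(self) -> phantom.PhantomConfig:
        return phantom.default_config(grid=self.grid, noise_sd_hu=self.noise_sd_hu,
                                      seed=self.seed)

    def augment_config(self) -> aug.AugmentConfig:
        # b-spline strength scaled to the desk grid (sigma 8 at 192^3 full
        # scale corresponds to ~1.3 voxels at 32^3)
        params = dict(bspline_control_points=6,
                      bspline_sigma=8.0 * self.grid / 192.0,
                      seed=self.seed)
        params.update(self.augment_params)
        return aug.AugmentConfig(**params)

    def stage_plan(self) -> list[str]:
        plan = ["simulate", "curate"]
        if "cyclegan" in self.conditions:
            plan += ["train-gan", "translate"]
        plan += ["train-seg+evaluate", "statistics", "report"]
        return plan


def _derive_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.default_rng(seed).integers(2**31 - 1, size=n)]


def run_experiment(config: ExperimentConfig, out_dir: str | Path | None = None,
                   dry_run: bool = False) -> dict:
    """Run the full desk-scale pipeline; deterministic in config.seed."""
    config.phantom_config().validate()
    config.augment_config().validate()
    if any(c not in aug.CONDITIONS for c in config.conditions):
        raise ValueError(f"unknown conditions in {config.conditions}")
    if dry_run:
        return {"stage_plan": config.stage_plan(), "config": asdict(config)}

    seeds = _derive_seeds(config.seed, 8)
    pc = config.phantom_config()
    jit = phantom.default_jitter()

    # -- simulate ------------------------------------------------------------
    in_cases = phantom.sample_dataset(pc, config.n_cases, seeds[0], jit, id_prefix="ind")
    ood_cases = phantom.sample_dataset(pc, config.n_ood, seeds[1], jit, id_prefix="ood")
    gan_cases = phantom.sample_dataset(pc, config.n_translator_cases, seeds[2], jit,
                                       id_prefix="gan")
    lab_cases = phantom.sample_dataset(pc, config.n_labeled_classifier, seeds[3], jit,
                                       id_prefix="lab")

    # -- curate --------------------------------------------------------------
    labeled = [(c.contrast_volume, "contrast") for c in lab_cases]
    labeled += [(c.noncontrast_volume, "noncontrast") for c in lab_cases]
    classifier = ct_io.train_contrast_classifier(labeled)
    # unpaired translator population: alternate domains across cases
    scan_volumes: dict[str, VolumeGrid] = {}
    records = []
    for i, case in enumerate(gan_cases):
        domain = "contrast" if i % 2 == 0 else "noncontrast"
        vol = case.volume(domain)
        scan_id = f"{case.case_id}_{domain}"
        scan_volumes[scan_id] = vol
        records.append(ct_io.CurationRecord(
            scan_id=scan_id,
            contrast_probability=classifier.contrast_probability(vol),
            fat_noise_sd_hu=ct_io.estimate_fat_noise(vol),
        ))
    pool_c, pool_n = ct_io.curate_translator_pools(records)

    translator = None
    translator_history: list[dict] = []
    translated: dict[str, VolumeGrid] = {}
    if "cyclegan" in config.conditions:
        # -- train-gan -------------------------------------------------------
        tparams = dict(seed=seeds[4])
        tparams.update(config.translator_params)
        translator = CycleGANTranslator(**tparams)
        translator.fit(
            [ct_io.preprocess(scan_volumes[r.scan_id]) for r in pool_c],
            [ct_io.preprocess(scan_volumes[r.scan_id]) for r in pool_n],
        )
        translator_history = translator.history_
        # -- translate (once, cached) ---------------------------------------
        for case in in_cases:
            translated[case.case_id] = translate_volume_hu(translator, case.contrast_volume)

    # -- cross-validated training and evaluation -----------------------------
    ids = [c.case_id for c in in_cases]
    by_id = {c.case_id: c for c in in_cases}
    folds = make_cv_folds(ids, k=config.k_folds, seed=seeds[5])
    policy = StoppingPolicy(max_iterations=config.max_iterations,
                            patience_epochs=config.patience_epochs)
    acfg = config.augment_config()
    all_records: list[EvalRecord] = []
    models: dict[tuple[str, int], UNet3DSegmenter] = {}
    ood_ids = {c.case_id for c in ood_cases}
    for fold in folds:
        assert not (set(fold.train_ids) | set(fold.val_ids)) & (set(fold.test_ids) | ood_ids), \
            "train/evaluation leakage"
        train = [by_id[i] for i in fold.train_ids]
        val = [by_id[i] for i in fold.val_ids]
        test = [by_id[i] for i in fold.test_ids]
        for condition in config.conditions:
            model = train_segmenter(
                train, val, condition, acfg, config.organ, policy,
                dict(config.unet_params), translated=translated or None,
                seed=seeds[6],
            )
            models[(condition, fold.fold_id)] = model
            all_records.extend(evaluate_fold(
                model, test, ood_cases, config.organ, condition, fold.fold_id
            ))

    # -- statistics ----------------------------------------------------------
    comparisons = []
    if {"standard", "cyclegan"} <= set(config.conditions):
        for domain in ("in_distribution", "out_of_distribution"):
            try:
                comparisons.append(paired_condition_comparison(
                    all_records, "standard", "cyclegan", domain))
            except ValueError as err:
                warnings.warn(f"comparison skipped for {domain}: {err}")

    summary = build_report(all_records)
    bundle = {
        "config": asdict(config),
        "records": [asdict(r) for r in all_records],
        "summary": summary,
        "comparisons": [asdict(c) for c in comparisons],
        "translator_history": translator_history,
        "curation": [asdict(r) for r in records],
        "models": models,
        "cases": {"in": in_cases, "ood": ood_cases},
        "translated": translated,
    }
    if out_dir is not None:
        _write_bundle(bundle, Path(out_dir))
    return bundle


def translator_toy_recovery(seed: int, iterations: int = 500,
                            enhancement_hu: float = 150.0) -> dict:
    """Constant-shift translation benchmark.

    A single kidney-like organ gains a flat ``enhancement_hu`` under
    contrast (no texture), so the non-contrast domain is the contrast
    domain minus a constant in organ regions. Trains the slice translator
    on unpaired pools and measures, on held-out cases, how much of the
    organ-mean intensity gap to the true non-contrast value the
    translation removes.
    """
    import dataclasses

    pc = phantom.default_config(grid=32, noise_sd_hu=10.0)
    kidney = next(o for o in pc.organs if o.name == "kidney")
    kidney = dataclasses.replace(kidney, texture_amplitude_hu=0.0,
                                 enhancement_hu=enhancement_hu)
    pc = dataclasses.replace(pc, organs=[kidney])
    jit = dataclasses.replace(phantom.default_jitter(), enhancement_hu=0.0)
    cases = phantom.sample_dataset(pc, 24, 5, jit)
    pool_a = [ct_io.preprocess(c.contrast_volume) for c in cases[:10]]
    pool_b = [ct_io.preprocess(c.noncontrast_volume) for c in cases[10:20]]
    translator = CycleGANTranslator(iterations=iterations, seed=seed).fit(pool_a, pool_b)
    reductions = []
    for case in cases[20:]:
        m = case.masks["kidney"].values.astype(bool)
        true_nc = case.noncontrast_volume.values[m].mean()
        before = abs(case.contrast_volume.values[m].mean() - true_nc)
        after = abs(translate_volume_hu(translator, case.contrast_volume).values[m].mean()
                    - true_nc)
        reductions.append(1.0 - after / before)
    return {
        "mean_gap_reduction": float(np.mean(reductions)),
        "cycle_loss_initial": translator.history_[0]["loss_cycle"],
        "cycle_loss_final": translator.history_[-1]["loss_cycle"],
        "n_held_out": len(reductions),
    }


def translate_volume_hu(translator: CycleGANTranslator, volume: VolumeGrid,
                        direction: str = "AtoB") -> VolumeGrid:
    """Translate an HU volume: clip, normalize, translate, map back to HU."""
    clipped = ct_io.clip_hu(volume)
    mean, sd = clipped.values.mean(), clipped.values.std()
    normalized = ct_io.normalize_zmuv(clipped)
    out = translator.transform(normalized, direction)
    hu = np.clip(out.values * sd + mean, *ct_io.HU_CLIP_RANGE)
    result = VolumeGrid(hu, volume.spacing_mm, HU, synthetic=True)
    return result


def _write_bundle(bundle: dict, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(bundle["records"]).to_csv(out_dir / "records.csv", index=False)
    bundle["summary"].to_csv(out_dir / "summary.csv", index=False)
    (out_dir / "report.md").write_text(report_markdown(bundle["summary"]) + "\n")
    meta = {
        "config": bundle["config"],
        "comparisons": bundle["comparisons"],
        "curation": bundle["curation"],
    }
    (out_dir / "experiment.json").write_text(json.dumps(meta, indent=2, default=str))
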