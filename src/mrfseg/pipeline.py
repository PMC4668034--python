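"""End-to-end orchestration: filter -> fit -> densities -> minimum-energy labels.

The library surface here is what the CLI wraps: `segment_stack` runs the
four-step method (or one of the baselines) on an in-memory stack,
`run_segmentation` / `run_benchmark` / `run_morphometry` add file IO and
CSV/JSON artifacts, and `benchmark_phantom_suite` scores all four methods
over a set of synthetic phantom seeds.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import baselines, density_model, evaluation, morphometry, mrf_core
from .entropy_filter import EntropyStack, local_entropy_stack
from .io_stack import (ImageStack, LabelMap, VoxelSpacing, read_labelmap,
                       read_stack, write_labelmap)
from .synthetic_phantom import PhantomSpec, generate_greyscale_phantom, generate_phantom

METHODS = ("mrf", "mixtures", "entotsu", "intotsu")

#: the beta working range; values outside it are accepted with a warning
BETA_WORKING_RANGE = (1.0 / 100.0, 1.0 / 10.0)


@dataclass
class RunConfig:
    """Everything a segmentation run needs, serialisable to a manifest."""

    channel_paths: list = field(default_factory=list)
    spacing: VoxelSpacing = field(default_factory=lambda: VoxelSpacing(10.0, 0.5, 0.5))
    method: str = "mrf"
    beta: float = mrf_core.DEFAULT_BETA
    entropy_window: int = 9
    eps: float = density_model.DEFAULT_EPS
    n_init: int = 10
    seed: int = 0
    neighbourhood: str = "6_3d"       # or "4_2d"
    max_sweeps: int = 10
    pooled_fit: bool = False
    #: path to a mixture_fits.json from a previous run; reusing one
    #: experiment's fits across its stacks skips refitting entirely
    fits_path: str | None = None
    out_dir: str = "."

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.neighbourhood not in ("6_3d", "4_2d"):
            raise ValueError("neighbourhood must be '6_3d' or '4_2d'")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if not BETA_WORKING_RANGE[0] <= self.beta <= BETA_WORKING_RANGE[1]:
            warnings.warn(f"beta={self.beta:g} is outside the working range "
                          f"[{BETA_WORKING_RANGE[0]:g}, {BETA_WORKING_RANGE[1]:g}]")

    def manifest(self) -> dict:
        return {
            "channel_paths": [str(p) for p in self.channel_paths],
            "spacing": [self.spacing.dz, self.spacing.dy, self.spacing.dx],
            "method": self.method, "beta": self.beta,
            "entropy_window": self.entropy_window, "eps": self.eps,
            "n_init": self.n_init, "seed": self.seed,
            "neighbourhood": self.neighbourhood, "max_sweeps": self.max_sweeps,
            "pooled_fit": self.pooled_fit,
            "fits_path": str(self.fits_path) if self.fits_path else None,
        }


@dataclass
class SegmentationResult:
    """Label map plus every intermediate a rerun or an audit needs."""

    labelmap: LabelMap
    entropy: EntropyStack
    fits: list                      # per-channel Mixture1D (reference fits)
    reference_slices: list          # per-channel reference slice index
    densities: density_model.LabelDensitySet | None
    unary: density_model.UnaryField | None
    energy_initial: float | None
    energy_final: float | None
    move_log: list
    timings: dict


def load_fits(path) -> tuple:
    """Load serialized mixture fits (the ``mixture_fits.json`` artifact)."""
    with open(path) as fh:
        payload = json.load(fh)
    fits = [density_model.Mixture1D.from_dict(d) for d in payload["fits"]]
    return fits, list(payload["reference_slices"])


def _fit_channels(entropy: EntropyStack, config: RunConfig):
    """Per-slice mixture fits, reference selection, per channel."""
    if config.fits_path:
        return load_fits(config.fits_path)
    fits, ref_slices = [], []
    nc = entropy.values.shape[-1]
    for c in range(nc):
        if config.pooled_fit:
            fit = density_model.fit_mixture_pooled(
                entropy, c, n_init=config.n_init, seed=config.seed + 1000 * c)
            fits.append(fit)
            ref_slices.append(0)
        else:
            slice_fits = density_model.fit_mixtures_per_slice(
                entropy, c, n_init=config.n_init, seed=config.seed + 1000 * c)
            ref = density_model.select_reference_image(slice_fits)
            fits.append(slice_fits[ref])
            ref_slices.append(ref)
    return fits, ref_slices


def _build_densities(fits, config: RunConfig):
    if len(fits) == 2:
        return density_model.build_label_densities(fits[0], fits[1],
                                                   eps=config.eps)
    return density_model.build_label_densities_1ch(fits[0], eps=config.eps)


def segment_stack(stack: ImageStack, config: RunConfig,
                  entropy: EntropyStack | None = None,
                  fitted: tuple | None = None) -> SegmentationResult:
    """Run the configured segmentation method on an in-memory stack.

    ``entropy`` and ``fitted`` (the ``(fits, ref_slices)`` pair from
    :func:`_fit_channels`) can be passed in to share the input-dependent
    stages across methods.
    """
    timings: dict = {}
    t0 = time.perf_counter()
    if entropy is None:
        entropy = local_entropy_stack(stack, window=config.entropy_window)
    timings["entropy_filter"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    fits, ref_slices = fitted if fitted is not None else _fit_channels(entropy, config)
    timings["mixture_fitting"] = time.perf_counter() - t0

    densities = unary = None
    energy_initial = energy_final = None
    move_log: list = []
    t0 = time.perf_counter()
    if config.method == "intotsu":
        labelmap = baselines.int_otsu_segment(stack, ref_slices[0],
                                              seed=config.seed)
    elif config.method == "entotsu":
        labelmap = baselines.ent_otsu_segment(entropy, ref_slices[0],
                                              seed=config.seed)
    else:
        densities = _build_densities(fits, config)
        unary = density_model.unary_potentials(entropy, densities)
        labelmap = baselines.mixtures_segment(entropy, densities)
        if config.method == "mrf":
            lam0, lam1 = mrf_core.set_lambdas(unary)
            offsets = (mrf_core.neighbour_offsets_6(stack.spacing.anisotropy)
                       if config.neighbourhood == "6_3d"
                       else mrf_core.neighbour_offsets_4())
            params = mrf_core.PairwiseParams(lam0, lam1, config.beta, offsets)
            model = mrf_core.EnergyModel(unary, params, entropy)
            energy_initial = mrf_core.total_energy(labelmap, model)
            labelmap = mrf_core.alpha_expansion(model, init=labelmap,
                                                max_sweeps=config.max_sweeps,
                                                seed=config.seed, log=move_log)
            energy_final = mrf_core.total_energy(labelmap, model)
    timings["labelling"] = time.perf_counter() - t0

    return SegmentationResult(labelmap, entropy, fits, ref_slices, densities,
                              unary, energy_initial, energy_final, move_log,
                              timings)


def merge_intermediate(labelmap: LabelMap) -> LabelMap:
    """Fold the single-channel 'intermediate' label (2) into background.

    Single-channel ground truth is binary; the out-of-focus label plays the
    same role the out-of-focus component plays in the two-channel
    densities — part of the background.
    """
    labels = labelmap.labels.copy()
    labels[labels == 2] = 0
    return LabelMap(labels, labelmap.spacing)


def run_segmentation(config: RunConfig) -> dict:
    """File-based segmentation run; writes label map, fits, log and manifest.

    Returns the artifact paths.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stack = read_stack(list(config.channel_paths), config.spacing)
    result = segment_stack(stack, config)

    paths = {"labelmap": out / "labels.tif", "fits": out / "mixture_fits.json",
             "energy_log": out / "energy.log", "manifest": out / "manifest.json"}
    write_labelmap(result.labelmap, paths["labelmap"])
    with open(paths["fits"], "w") as fh:
        json.dump({"reference_slices": result.reference_slices,
                   "fits": [f.to_dict() for f in result.fits]}, fh, indent=2)
    with open(paths["energy_log"], "w") as fh:
        fh.write(f"energy_initial\t{result.energy_initial}\n")
        for alpha, delta in result.move_log:
            fh.write(f"accepted\talpha={alpha}\tdelta_energy={delta:.6f}\n")
        fh.write(f"energy_final\t{result.energy_final}\n")
    with open(paths["manifest"], "w") as fh:
        json.dump(config.manifest(), fh, indent=2)
    return {k: str(v) for k, v in paths.items()}


def _summary_rows(df: pd.DataFrame) -> pd.DataFrame:
    """Mean and median macro-F1 per method, appended as summary rows."""
    rows = []
    for stat, fn in (("mean", np.mean), ("median", np.median)):
        for method in df["method"].unique():
            sub = df[df["method"] == method]
            rows.append({"stack": stat, "method": method,
                         "macro_f1": fn(sub["macro_f1"].to_numpy()),
                         "macro_precision": fn(sub["macro_precision"].to_numpy()),
                         "macro_recall": fn(sub["macro_recall"].to_numpy())})
    return pd.DataFrame(rows)


def benchmark_stacks(items: list, config: RunConfig,
                     methods: tuple = METHODS) -> pd.DataFrame:
    """Score every method on every (name, stack, truth) triple.

    The entropy filter and mixture fits are shared across methods for each
    stack (they only depend on the input), so the four methods differ purely
    in the labelling step.
    """
    records = []
    for name, stack, truth in items:
        entropy = local_entropy_stack(stack, window=config.entropy_window)
        fitted = _fit_channels(entropy, config)
        for method in methods:
            cfg = _with_method(config, method)
            result = segment_stack(stack, cfg, entropy=entropy, fitted=fitted)
            pred = result.labelmap
            if stack.data.shape[-1] == 1:
                pred = merge_intermediate(pred)
                scores = evaluation.score_labelmaps(pred, truth, labels=(0, 1))
            else:
                scores = evaluation.score_labelmaps(pred, truth)
            records.append({
                "stack": name, "method": method,
                "macro_f1": scores.macro_f1,
                "macro_precision": scores.macro_precision,
                "macro_recall": scores.macro_recall,
                "mean_class_f1": scores.mean_class_f1,
            })
    df = pd.DataFrame(records)
    return pd.concat([df, _summary_rows(df)], ignore_index=True)


def _with_method(config: RunConfig, method: str) -> RunConfig:
    kwargs = config.manifest()
    kwargs.pop("channel_paths")
    kwargs.pop("spacing")
    return RunConfig(channel_paths=config.channel_paths, spacing=config.spacing,
                     out_dir=config.out_dir, **{**kwargs, "method": method})


def run_benchmark(stack_dirs: list, config: RunConfig,
                  truth_name: str = "truth.tif") -> pd.DataFrame:
    """Benchmark all methods over a directory layout of stacks + truth.

    Each entry of ``stack_dirs`` must contain ``red.tif``/``green.tif`` (or a
    single ``grey.tif``) and the ground-truth label map ``truth.tif``.
    """
    items = []
    for d in stack_dirs:
        d = Path(d)
        truth_path = d / truth_name
        if not truth_path.exists():
            raise FileNotFoundError(f"missing ground truth: {truth_path}")
        if (d / "red.tif").exists():
            stack = read_stack([d / "red.tif", d / "green.tif"], config.spacing)
        else:
            stack = read_stack([d / "grey.tif"], config.spacing,
                               channel_names=["grey"])
        truth = read_labelmap(truth_path, config.spacing)
        items.append((d.name, stack, truth))
    return benchmark_stacks(items, config)


def run_morphometry(labelmaps: list) -> pd.DataFrame:
    """ContactStats per (name, LabelMap) pair as a tidy table."""
    rows = []
    for name, lm in labelmaps:
        rows.append({"stack": name, **morphometry.contact_stats(lm).as_dict()})
    return pd.DataFrame(rows)


def benchmark_phantom_suite(seeds, base_spec: PhantomSpec | None = None,
                            config: RunConfig | None = None) -> pd.DataFrame:
    """Generate one two-channel phantom per seed and benchmark all methods."""
    config = config or RunConfig()
    items = []
    for seed in seeds:
        spec = base_spec or PhantomSpec()
        spec = PhantomSpec(**{**spec.__dict__, "seed": int(seed)})
        stack, truth = generate_phantom(spec)
        items.append((f"phantom_seed{seed}", stack, truth))
    return benchmark_stacks(items, config)


def segment_greyscale_phantom(seed: int, config: RunConfig | None = None):
    """Single-channel 2D phantom through the 4-neighbour MRF; returns scores."""
    if config is None:
        config = RunConfig(neighbourhood="4_2d", seed=int(seed))
    spec = PhantomSpec(seed=int(seed))
    stack, truth = generate_greyscale_phantom(spec)
    result = segment_stack(stack, config)
    pred = merge_intermediate(result.labelmap)
    # binary truth: macro-average over the two classes that exist
    return evaluation.score_labelmaps(pred, truth, labels=(0, 1)), result
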