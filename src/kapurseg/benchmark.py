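"""Experiment harness: repeated runs, median score tables and win counts.

The comparison protocol standard in the multilevel-thresholding literature
is followed: every (image, threshold count, algorithm) case is run for a
number of independent repeats (10, population 30, 100 iterations) and the
*median* best fitness is tabulated; for an even repeat count the
lower-middle order statistic is taken.  An algorithm "wins" a table row when
its cell equals the row optimum; ties count as a win for every tied
algorithm.

The package ships reference score tables from the published CIWP-PSO
comparison study (medians over 10 runs on nine 12-bit MRI images and
sixteen 12-bit benchmark images, at 4/6/8 thresholds) as CSV fixtures, so
win counts can be recomputed from the printed numbers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .ciwp import run_ciwp_pso
from .histogram import GrayImage, KapurObjective, compute_histogram, render_segmented
from .metrics import compute_metrics
from .pso import RunResult, SwarmConfig, run_pso
from .synthetic import MixtureSpec, generate_synthetic_image

__all__ = [
    "ScoreTable",
    "BenchmarkConfig",
    "ALGORITHMS",
    "load_reference_table",
    "run_benchmark",
    "count_wins",
    "export_convergence",
]

#: Registered optimizers; the registry order keys the per-run seed streams,
#: so appending a new algorithm never perturbs existing ones.
ALGORITHMS: dict[str, Callable[[KapurObjective, SwarmConfig, np.random.Generator], RunResult]] = {
    "pso": lambda obj, cfg, rng: run_pso(obj, cfg, rng),
    "ciwp-pso": lambda obj, cfg, rng: run_ciwp_pso(obj, cfg, rng),
}

_REFERENCE_TABLES = {
    "mri-kapur": "mri_kapur_medians.csv",
    "mri-psnr": "mri_psnr_medians.csv",
    "mri-ssim": "mri_ssim_medians.csv",
    "mri-fsim": "mri_fsim_medians.csv",
    "benchmark-kapur": "benchmark_kapur_medians.csv",
}


@dataclass
class ScoreTable:
    """Rectangular (case x algorithm) score matrix.

    Rows are keyed by ``(image_id, n_thresholds)``; every cell must be
    present.  ``higher_is_better`` fixes the orientation for win counting
    (True for entropy/PSNR/SSIM/FSIM).
    """

    data: pd.DataFrame
    higher_is_better: bool = True

    def __post_init__(self) -> None:
        df = self.data
        if not {"image_id", "n_thresholds"}.issubset(df.columns):
            raise ValueError("table needs image_id and n_thresholds columns")
        if df.duplicated(["image_id", "n_thresholds"]).any():
            raise ValueError("row keys must be unique")
        if df[self.algorithms].isna().any().any():
            raise ValueError("table has missing cells")

    @property
    def algorithms(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("image_id", "n_thresholds")]

    @property
    def n_rows(self) -> int:
        return len(self.data)

    @classmethod
    def from_csv(cls, path: str | Path, higher_is_better: bool = True) -> "ScoreTable":
        return cls(pd.read_csv(path), higher_is_better=higher_is_better)

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


def load_reference_table(name: str) -> ScoreTable:
    """Load one of the packaged reference score tables.

    Names: ``mri-kapur`` (27 x 9), ``mri-psnr`` / ``mri-ssim`` /
    ``mri-fsim`` (27 x 6), ``benchmark-kapur`` (48 x 9).
    """
    try:
        fname = _REFERENCE_TABLES[name]
    except KeyError:
        raise KeyError(f"unknown table {name!r}; choose from {sorted(_REFERENCE_TABLES)}")
    with resources.files("kapurseg.data").joinpath(fname).open("r") as f:
        return ScoreTable(pd.read_csv(f))


def count_wins(table: ScoreTable, algorithm: str) -> int:
    """Number of rows where ``algorithm`` attains the row optimum.

    Ties count as a win for every tied algorithm — the convention under
    which the packaged reference tables reproduce their published win
    counts.  Cells are compared exactly (the fixtures carry full printed
    precision, so tied entries are digit-identical).
    """
    if algorithm not in table.algorithms:
        raise KeyError(f"{algorithm!r} is not a column of the table")
    scores = table.data[table.algorithms]
    best = scores.max(axis=1) if table.higher_is_better else scores.min(axis=1)
    return int((scores[algorithm] == best).sum())


@dataclass
class BenchmarkConfig:
    """Specification of a full benchmark sweep.

    ``images`` maps image ids either to file paths or to
    :class:`~kapurseg.synthetic.MixtureSpec` recipes.  Seeds are derived
    deterministically per (image, n_thresholds, algorithm, repeat).
    """

    images: dict[str, str | Path | MixtureSpec]
    n_thresholds_list: Sequence[int] = (4, 6, 8)
    algorithms: Sequence[str] = ("pso", "ciwp-pso")
    repeats: int = 10
    base_seed: int = 0
    swarm: dict = field(default_factory=dict)  # extra SwarmConfig overrides

    def __post_init__(self) -> None:
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        unknown = set(self.algorithms) - set(ALGORITHMS)
        if unknown:
            raise KeyError(f"unknown algorithm(s): {sorted(unknown)}")


def _load_image(source: str | Path | MixtureSpec) -> GrayImage:
    if isinstance(source, MixtureSpec):
        return generate_synthetic_image(source)
    from .io import read_image

    return read_image(source)


def _median_run(results: list[RunResult]) -> RunResult:
    """The run achieving the median fitness (lower-middle for even counts)."""
    order = np.argsort([r.best_fitness for r in results], kind="stable")
    return results[order[(len(results) - 1) // 2]]


def run_benchmark(config: BenchmarkConfig) -> tuple[ScoreTable, dict, pd.DataFrame]:
    """Execute the sweep; returns the median-fitness table, the median-run
    convergence curves keyed by (image_id, n_thresholds, algorithm), and a
    tidy metrics table for the median runs' rendered segmentations."""
    rows = []
    curves: dict[tuple[str, int, str], np.ndarray] = {}
    metric_rows = []
    alg_index = {name: i for i, name in enumerate(ALGORITHMS)}
    for img_i, (image_id, source) in enumerate(config.images.items()):
        image = _load_image(source)
        hist = compute_histogram(image)
        objective = KapurObjective(hist)
        for nth in config.n_thresholds_list:
            row: dict = {"image_id": image_id, "n_thresholds": nth}
            for alg in config.algorithms:
                runner = ALGORITHMS[alg]
                results = []
                for rep in range(config.repeats):
                    ss = np.random.SeedSequence(
                        entropy=config.base_seed,
                        spawn_key=(img_i, nth, alg_index[alg], rep),
                    )
                    cfg = SwarmConfig.for_levels(hist.levels, nth, **config.swarm)
                    results.append(runner(objective, cfg, np.random.default_rng(ss)))
                med = _median_run(results)
                row[alg] = med.best_fitness
                curves[(image_id, nth, alg)] = med.convergence
                rendered = render_segmented(image, med.best_thresholds)
                report = compute_metrics(image, rendered)
                metric_rows.append(
                    {
                        "image_id": image_id,
                        "n_thresholds": nth,
                        "algorithm": alg,
                        "psnr": report.psnr_db,
                        "ssim": report.ssim,
                        "fsim": report.fsim,
                    }
                )
            rows.append(row)
    table = ScoreTable(pd.DataFrame(rows))
    return table, curves, pd.DataFrame(metric_rows)


def export_convergence(
    result: RunResult | np.ndarray, path: str | Path, plot: bool = False
) -> None:
    """Write a (iteration, best_so_far) CSV; floats use shortest round-trip
    repr so re-exporting the same run is byte-identical."""
    curve = result.convergence if isinstance(result, RunResult) else np.asarray(result)
    path = Path(path)
    with open(path, "w", newline="") as f:
        f.write("iteration,best_so_far\n")
        for i, v in enumerate(curve):
            f.write(f"{i},{float(v)!r}\n")
    if plot:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots()
        ax.plot(np.arange(len(curve)), curve)
        ax.set_xlabel("iteration")
        ax.set_ylabel("best-so-far Kapur entropy")
        fig.savefig(path.with_suffix(".png"), dpi=120)
        plt.close(fig)
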