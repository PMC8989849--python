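"""End-to-end experiment: simulate cohort, extract features, train, score.

Reproduces the study protocol on synthetic data: per subject, 80 labeled
trials are split 40 train / 40 test, each of the three feature families is
fed to both classifiers (single C4.5 tree; improved random forest), and the
per-subject accuracies are collected into a subjects x families x classifiers
grid with grand means per (family, classifier) cell.

The split is a seeded stratified shuffle by default; ``sequential`` takes the
first half as training, matching a literal fixed-order reading of the
protocol.  ``n_repeats > 1`` averages over repeated splits to tame the ~8%
binomial noise of a 40-item test set.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .entropy import SampleEntropyParams
from .features import FEATURE_SETS, extract_feature_tables, split_feature_frame
from .wavelet import WaveletPacketConfig
from .forest import ImprovedRandomForestClassifier
from .segments import SubjectSpec
from .synthetic import default_subject_spec, generate_cohort
from .tree import C45TreeClassifier

__all__ = [
    "ExperimentConfig",
    "ResultGrid",
    "split_dataset",
    "evaluate_accuracy",
    "run_experiment",
    "render_report",
]

logger = logging.getLogger(__name__)

CLASSIFIERS = ("c45_tree", "improved_forest")


@dataclass(frozen=True)
class ExperimentConfig:
    """Cohort, feature, classifier, and protocol settings for one experiment."""

    n_subjects: int = 10
    n_segments: int = 80
    separation: float = 1.0
    noise_sd: float = 8.0
    fs: float = 1000.0
    duration: float = 2.0
    seed: int = 0
    feature_sets: tuple[str, ...] = FEATURE_SETS
    wavelet_name: str = "db4"
    levels: int = 4
    cutoff_hz: float = 256.0
    target_fs: float = 512.0
    entropy_m: int = 2
    entropy_r_factor: float = 0.2
    entropy_scale: int = 2
    split_rule: str = "stratified"  # or "sequential"
    train_fraction: float = 0.5
    n_repeats: int = 1
    tree_params: dict = field(default_factory=dict)
    forest_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.split_rule not in ("stratified", "sequential"):
            raise ValueError("split_rule must be 'stratified' or 'sequential'")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        unknown = set(self.feature_sets) - set(FEATURE_SETS)
        if unknown:
            raise ValueError(f"unknown feature sets: {sorted(unknown)}")

    def base_spec(self) -> SubjectSpec:
        return default_subject_spec(
            n_segments=self.n_segments,
            noise_sd=self.noise_sd,
            fs=self.fs,
            duration=self.duration,
            seed=self.seed,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def split_dataset(
    table: pd.DataFrame,
    rule: str = "stratified",
    seed: int | None = 0,
    train_fraction: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive train/test split of a feature table.

    ``stratified``: seeded shuffle within each class, then the first
    ``train_fraction`` of each class's rows go to training (class-balanced by
    construction).  ``sequential``: the first ``train_fraction`` of rows in
    file order are training.  Both classes must appear in the training split.
    """
    if rule == "stratified":
        rng = np.random.default_rng(seed)
        train_idx: list[int] = []
        test_idx: list[int] = []
        for label in sorted(table["label"].unique()):
            rows = np.nonzero((table["label"] == label).to_numpy())[0]
            rows = rows[rng.permutation(rows.size)]
            k = int(round(train_fraction * rows.size))
            train_idx.extend(rows[:k].tolist())
            test_idx.extend(rows[k:].tolist())
        train = table.iloc[sorted(train_idx)]
        test = table.iloc[sorted(test_idx)]
    elif rule == "sequential":
        k = int(round(train_fraction * len(table)))
        train, test = table.iloc[:k], table.iloc[k:]
    else:
        raise ValueError("rule must be 'stratified' or 'sequential'")
    if train["label"].nunique() < 2 or len(test) == 0:
        raise ValueError("degenerate split: training set must contain both classes")
    return train, test


def evaluate_accuracy(model, X_test, y_test) -> float:
    """Fraction of correct predictions on the test set."""
    y_test = np.asarray(y_test, dtype=object).ravel()
    if y_test.size == 0:
        raise ValueError("empty test set")
    predictions = np.asarray(model.predict(X_test), dtype=object)
    return float(np.mean(predictions == y_test))


@dataclass
class ResultGrid:
    """Long-format accuracy table with grid and grand-mean views.

    ``frame`` columns: subject, feature_set, classifier, repeat, accuracy,
    n_test.
    """

    frame: pd.DataFrame
    config: ExperimentConfig

    def cell(self, subject: str, feature_set: str, classifier: str) -> float:
        """Per-subject accuracy (mean over repeats)."""
        f = self.frame
        sel = f[
            (f.subject == subject)
            & (f.feature_set == feature_set)
            & (f.classifier == classifier)
        ]
        if sel.empty:
            raise KeyError((subject, feature_set, classifier))
        return float(sel.accuracy.mean())

    def grid(self, classifier: str) -> pd.DataFrame:
        """Feature-family rows x subject columns (plus Mean), one classifier."""
        f = self.frame[self.frame.classifier == classifier]
        if f.empty:
            raise KeyError(classifier)
        pivot = f.pivot_table(
            index="feature_set", columns="subject", values="accuracy", aggfunc="mean"
        )
        pivot = pivot.reindex(index=[fs for fs in self.config.feature_sets])
        pivot["Mean"] = pivot.mean(axis=1)
        return pivot

    def grand_means(self) -> pd.DataFrame:
        """Mean accuracy per (feature_set, classifier) over subjects and repeats."""
        return self.frame.pivot_table(
            index="feature_set",
            columns="classifier",
            values="accuracy",
            aggfunc="mean",
        ).reindex(index=[fs for fs in self.config.feature_sets])

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def _make_models(config: ExperimentConfig, seed: int) -> dict:
    forest_params = dict(config.forest_params)
    forest_params.setdefault("random_state", seed)
    return {
        "c45_tree": C45TreeClassifier(**config.tree_params),
        "improved_forest": ImprovedRandomForestClassifier(**forest_params),
    }


def run_experiment(
    config: ExperimentConfig | None = None, run_dir: str | Path | None = None
) -> ResultGrid:
    """Full protocol: cohort -> features -> per-subject train/test -> grid.

    With ``run_dir`` set, writes ``config.json``, per-subject feature tables,
    and ``results.csv`` into that directory.
    """
    config = config or ExperimentConfig()
    t0 = time.perf_counter()
    cohort = generate_cohort(
        config.n_subjects, config.base_spec(), config.separation
    )
    logger.info("cohort simulated in %.1fs", time.perf_counter() - t0)

    out_dir = None
    if run_dir is not None:
        out_dir = Path(run_dir)
        (out_dir / "features").mkdir(parents=True, exist_ok=True)
        (out_dir / "config.json").write_text(
            json.dumps(config.to_dict(), indent=2) + "\n"
        )

    records = []
    for s_index, segments in enumerate(cohort):
        subject = segments[0].subject_id
        t0 = time.perf_counter()
        tables = extract_feature_tables(
            segments,
            config.feature_sets,
            wp_config=WaveletPacketConfig(config.wavelet_name, config.levels),
            entropy_params=SampleEntropyParams(
                config.entropy_m, config.entropy_r_factor, config.entropy_scale
            ),
            cutoff_hz=config.cutoff_hz,
            target_fs=config.target_fs,
        )
        logger.info(
            "%s: features extracted in %.1fs", subject, time.perf_counter() - t0
        )
        for fs_name, table in tables.items():
            if out_dir is not None:
                table.to_csv(out_dir / "features" / f"{subject}_{fs_name}.csv",
                             index=False)
            for rep in range(config.n_repeats):
                split_seed = int(
                    np.random.SeedSequence(
                        [config.seed, s_index, rep]
                    ).generate_state(1)[0]
                    & 0x7FFFFFFF
                )
                try:
                    train, test = split_dataset(
                        table, config.split_rule, split_seed, config.train_fraction
                    )
                except ValueError as exc:
                    raise ValueError(f"subject {subject}: {exc}") from exc
                X_train, y_train = split_feature_frame(train)
                X_test, y_test = split_feature_frame(test)
                for clf_name, model in _make_models(config, split_seed).items():
                    model.fit(X_train, y_train)
                    acc = evaluate_accuracy(model, X_test, y_test)
                    records.append(
                        dict(
                            subject=subject,
                            feature_set=fs_name,
                            classifier=clf_name,
                            repeat=rep,
                            accuracy=acc,
                            n_test=len(test),
                        )
                    )

    grid = ResultGrid(frame=pd.DataFrame.from_records(records), config=config)
    if out_dir is not None:
        grid.to_csv(out_dir / "results.csv")
    return grid


def _markdown_table(pivot: pd.DataFrame) -> str:
    header = [str(pivot.index.name or "")] + [str(c) for c in pivot.columns]
    lines = ["| " + " | ".join(header) + " |",
             "|" + "|".join("---" for _ in header) + "|"]
    for idx, row in pivot.iterrows():
        cells = [str(idx)] + [f"{v:.4f}" for v in row]
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines) + "\n"


def render_report(grid: ResultGrid, out_dir: str | Path) -> list[Path]:
    """Write per-classifier accuracy tables (CSV + markdown) and bar charts.

    Returns the list of files written.
    """
    if grid.frame.empty:
        raise ValueError("cannot render a report from an empty result grid")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    for clf in CLASSIFIERS:
        if clf not in set(grid.frame.classifier):
            continue
        pivot = grid.grid(clf)
        csv_path = out / f"accuracy_{clf}.csv"
        pivot.to_csv(csv_path)
        md_path = out / f"accuracy_{clf}.md"
        md_path.write_text(_markdown_table(pivot))
        written += [csv_path, md_path]

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for fs_name in grid.config.feature_sets:
        sub = grid.frame[grid.frame.feature_set == fs_name]
        if sub.empty:
            continue
        pivot = sub.pivot_table(
            index="subject", columns="classifier", values="accuracy", aggfunc="mean"
        )
        ax = pivot.plot.bar(figsize=(8, 4), rot=0)
        ax.set_ylabel("test accuracy")
        ax.set_ylim(0, 1.05)
        ax.set_title(f"Per-subject accuracy, feature family {fs_name!r}")
        fig_path = out / f"accuracy_{fs_name}.png"
        ax.figure.tight_layout()
        ax.figure.savefig(fig_path, dpi=120)
        plt.close(ax.figure)
        written.append(fig_path)
    return written
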