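"""Run manifests and table-style summaries (histograms, trajectories).

All outputs are plain TSV/YAML so headless runs are complete; figures, if
wanted, are derivable from these tables.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .experiment import ScenarioConfig
from .relationships import RelationshipMatrix, coancestry_summary

try:  # single source of truth for the version
    from importlib.metadata import version as _pkg_version

    _VERSION = _pkg_version("coansel")
except Exception:  # pragma: no cover
    _VERSION = "unknown"


@dataclass
class RunManifest:
    """Everything needed to reproduce a run bit-for-bit with the same code."""

    configs: list[dict]
    seed: int
    n_replicates: int
    replicate_seeds: list[int]
    version: str = _VERSION
    created: str = ""

    @classmethod
    def for_run(
        cls, configs: list[ScenarioConfig], seed: int, n_replicates: int
    ) -> "RunManifest":
        return cls(
            configs=[c.to_dict() for c in configs],
            seed=int(seed),
            n_replicates=int(n_replicates),
            replicate_seeds=[(seed + r) % 2**31 for r in range(n_replicates)],
            created=datetime.datetime.now().isoformat(timespec="seconds"),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.__dict__, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunManifest":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def scenario_configs(self) -> list[ScenarioConfig]:
        return [ScenarioConfig(**d) for d in self.configs]


def coancestry_histograms(
    matrices: dict[str, RelationshipMatrix], bins: int = 30
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Binned off-diagonal coancestry counts per matrix kind.

    Returns a long table (kind, bin_left, bin_right, count) plus the
    per-kind variance of the binned coancestries.
    """
    rows = []
    variances = {}
    for kind, mat in matrices.items():
        s = coancestry_summary(mat, bins=bins)
        variances[kind] = s.var_coancestry
        for left, right, count in zip(
            s.hist_edges[:-1], s.hist_edges[1:], s.hist_counts
        ):
            rows.append(
                {
                    "kind": kind,
                    "bin_left": float(left),
                    "bin_right": float(right),
                    "count": int(count),
                }
            )
    return pd.DataFrame(rows), variances


def trajectory_table(per_replicate: pd.DataFrame, metric: str) -> pd.DataFrame:
    """Replicate-mean trajectory of one metric, scenarios as columns."""
    return (
        per_replicate.groupby(["generation", "scenario"])[metric]
        .mean()
        .unstack("scenario")
    )


def write_metrics(
    out_dir: str | Path,
    per_replicate: pd.DataFrame,
    aggregated: pd.DataFrame,
    manifest: RunManifest,
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    per_replicate.to_csv(out / "metrics.tsv", sep="\t", index=False)
    aggregated.to_csv(out / "aggregate.tsv", sep="\t", index=False)
    manifest.to_yaml(out / "manifest.yaml")
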