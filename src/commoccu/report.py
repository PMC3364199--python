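"""Publication-style output tables and run manifests."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .detection import DetectionDataset, naive_occupancy
from .diagnostics import model_averaged_summary, posterior_model_table
from .sampler import PosteriorSamples

__all__ = ["render_species_table", "render_model_table", "RunManifest"]


def render_species_table(data: DetectionDataset, samples: PosteriorSamples) -> pd.DataFrame:
    """One row per species: naive occurrence, psi (sd), p (sd), effect flags.

    Column order is fixed so repeated runs diff cleanly.
    """
    summary = model_averaged_summary(samples)["species"]
    naive = naive_occupancy(data)
    table = pd.DataFrame(
        {
            "species": summary["species"],
            "naive_occupancy": naive.loc[summary["species"]].to_numpy(),
            "psi": summary["psi_mean"].round(3),
            "psi_sd": summary["psi_sd"].round(3),
            "p": summary["p_mean"].round(3),
            "p_sd": summary["p_sd"].round(3),
            "covariate_effects": summary["effects"],
        }
    )
    return table.sort_values("naive_occupancy", ascending=False).reset_index(drop=True)


def render_model_table(model_table: pd.DataFrame, top: int | None = None) -> pd.DataFrame:
    """Ranked candidate models as psi(...) p(...) formula strings."""
    out = model_table[["model", "posterior_probability"]].copy()
    out["posterior_probability"] = out["posterior_probability"].round(3)
    if top is not None:
        out = out.head(top)
    return out.reset_index(drop=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Enough metadata to reproduce a run exactly."""

    seed: int
    config: dict = field(default_factory=dict)
    input_checksums: dict[str, str] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    package_version: str = ""

    def add_input(self, path: str | Path) -> None:
        p = Path(path)
        self.input_checksums[p.name] = _sha256(p)

    def write(self, path: str | Path) -> None:
        if not self.package_version:
            from . import __version__

            self.package_version = __version__
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1))

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
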