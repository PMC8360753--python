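"""Round-trip file I/O and run manifests for the command-line tools.

All formats are delimited text (TSV by default): microarray-scale data
are small enough that auditability beats binary containers.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .data import ExpressionDataset, read_expression, read_response
from .gibbs import ChainResult
from .graph import GeneNetwork

__all__ = [
    "RunManifest",
    "load_dataset",
    "write_expression",
    "write_response",
    "write_edge_list",
    "write_trace",
]


@dataclass
class RunManifest:
    """Everything needed to reproduce a run: inputs, config, version."""

    command: str
    inputs: dict
    config: dict
    version: str = ""
    platform: str = field(default_factory=platform.platform)
    started: str = ""
    finished: str = ""

    def start(self) -> "RunManifest":
        self.started = datetime.now(timezone.utc).isoformat()
        return self

    def finish(self) -> "RunManifest":
        self.finished = datetime.now(timezone.utc).isoformat()
        return self

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def load_dataset(
    expression_path: str | Path,
    response_path: str | Path,
    response_column: str | None = None,
    sep: str = "\t",
) -> ExpressionDataset:
    """Read expression + response files into an aligned dataset.

    When the response file carries sample identifiers they are matched
    against the expression matrix's rows; a plain one-value-per-line
    file is taken to be in expression row order.
    """
    df, gene_ids, sample_ids = read_expression(expression_path, sep=sep)
    resp = read_response(response_path, column=response_column, sep=sep)
    if response_column is not None or set(resp.index) & set(sample_ids):
        missing = [s for s in sample_ids if s not in resp.index]
        extra = [s for s in resp.index if s not in sample_ids]
        if missing or extra:
            raise ValueError(
                f"sample identifiers misaligned between expression and response: "
                f"missing from response {missing[:5]}, unknown in response {extra[:5]}"
            )
        y = resp.loc[sample_ids].to_numpy()
    else:
        if len(resp) != len(sample_ids):
            raise ValueError(
                f"response has {len(resp)} values but expression has {len(sample_ids)} samples"
            )
        y = resp.to_numpy()
    return ExpressionDataset(
        X=df.to_numpy(dtype=float), y=y, gene_ids=gene_ids, sample_ids=sample_ids
    )


def write_expression(data: ExpressionDataset, path: str | Path) -> None:
    pd.DataFrame(data.X, index=pd.Index(data.sample_ids, name="sample_id"),
                 columns=data.gene_ids).to_csv(path, sep="\t", float_format="%.12g")


def write_response(data: ExpressionDataset, path: str | Path) -> None:
    pd.Series(data.y).to_csv(path, sep="\t", header=False, index=False,
                             float_format="%.12g")


def write_edge_list(net: GeneNetwork, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("# gene_a\tgene_b\tweight\n")
        for u, v, w in net.graph.edges(data="weight", default=1.0):
            fh.write(f"{u}\t{v}\t{w:.12g}\n")


def write_trace(result: ChainResult, path: str | Path) -> None:
    """Log-joint trace, one value per sweep (burn-in included)."""
    np.savetxt(path, result.log_joint_trace, fmt="%.10g",
               header="log_joint per iteration", comments="# ")
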