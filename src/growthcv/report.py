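"""Publication-style rendering of comparison tables and run manifests."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def render_comparison(table: pd.DataFrame, decimals: int = 2) -> str:
    """Aligned-text rendering of a model-comparison table.

    One row per dataset, one column per model x scale arm; the per-row
    minimum is flagged with an asterisk (cells tied with the minimum at
    the printed precision are all flagged), failed arms render blank, and
    a footnote counts failures.
    """
    if len(table) == 0:
        raise ValueError("empty comparison table")
    arm_cols = [c for c in table.columns
                if c != "min_arm" and not c.startswith("failures[")
                and not c.startswith("dataset")]
    name_col = [c for c in table.columns if c.startswith("dataset")]
    lines = []
    header = (["dataset"] if name_col else []) + arm_cols
    cells_rows = []
    for _, row in table.iterrows():
        vals = np.array([row[c] for c in arm_cols], float)
        finite = np.isfinite(vals)
        best = vals[finite].min() if finite.any() else np.nan
        cells = []
        for v in vals:
            if not np.isfinite(v):
                cells.append("")
            else:
                tied = round(v, decimals) == round(best, decimals)
                cells.append(f"{v:.{decimals}f}{'*' if tied else ''}")
        if name_col:
            cells = [str(row[name_col[0]])] + cells
        cells_rows.append(cells)
    widths = [max(len(h), *(len(r[i]) for r in cells_rows))
              for i, h in enumerate(header)]
    lines.append("  ".join(h.ljust(w) for h, w in zip(header, widths)))
    lines.append("  ".join("-" * w for w in widths))
    for cells in cells_rows:
        lines.append("  ".join(c.ljust(w) for c, w in zip(cells, widths)))
    fail_cols = [c for c in table.columns if c.startswith("failures[")]
    notes = []
    for c in fail_cols:
        total = int(table[c].sum())
        if total:
            arm = c[len("failures["):-1]
            notes.append(f"{arm}: {total} failure(s)")
    if notes:
        lines.append("")
        lines.append("blank cells / failures -- " + "; ".join(notes))
    return "\n".join(lines)


def comparison_to_csv(table: pd.DataFrame, path) -> None:
    """Full-precision CSV of a comparison table."""
    table.to_csv(path, index=False)


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Everything needed to re-run a command bit-identically."""

    command: str
    config: dict
    seed: int
    package_version: str
    input_digests: dict = field(default_factory=dict)
    status: list = field(default_factory=list)

    def add_input(self, path) -> None:
        self.input_digests[str(path)] = _digest(path)

    def log(self, message: str) -> None:
        self.status.append(message)

    def write(self, path) -> None:
        doc = {
            "command": self.command,
            "config": self.config,
            "seed": self.seed,
            "package_version": self.package_version,
            "input_digests": self.input_digests,
            "status": self.status,
        }
        with open(path, "w") as f:
            json.dump(doc, f, indent=1, sort_keys=True)
            f.write("\n")
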