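"""Optional scatterplots for the exploratory baseline-covariate screen."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .stats import DEFAULT_COVARIATES


def screen_scatterplots(tbl: pd.DataFrame, out_dir: str | Path,
                        covariates: tuple[str, ...] | None = None,
                        outcome: str = "d_icp") -> list[Path]:
    """One scatterplot per baseline covariate vs the ICP change."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    covariates = DEFAULT_COVARIATES if covariates is None else covariates

    d = tbl[tbl["label"] == "intervention"]
    base = tbl[tbl["label"] == "baseline"].set_index(["animal", "block"])
    paths = []
    for cov in covariates:
        if cov not in tbl.columns:
            continue
        x = [base[cov].get((a, b), float("nan"))
             for a, b in zip(d["animal"], d["block"])]
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.scatter(x, d[outcome], s=14, alpha=0.7)
        ax.set_xlabel(f"baseline {cov}")
        ax.set_ylabel(outcome)
        fig.tight_layout()
        p = out_dir / f"screen_{cov}.png"
        fig.savefig(p, dpi=100)
        plt.close(fig)
        paths.append(p)
    return paths
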