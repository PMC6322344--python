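"""Optional matplotlib figures over the exported diagnostic series."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from dentalrisk.bayes import PosteriorSamples
from dentalrisk.diagnostics import ConvergenceReport, autocorrelation

__all__ = ["plot_diagnostics"]


def plot_diagnostics(
    samples: PosteriorSamples,
    report: ConvergenceReport,
    out_dir: str | Path,
    max_lag: int = 30,
) -> list[Path]:
    """One trace/density/ACF panel row per coefficient slot, saved as PNGs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for j, name in enumerate(samples.names):
        fig, axes = plt.subplots(1, 3, figsize=(10, 2.6))
        for c in range(samples.n_chains):
            axes[0].plot(samples.draws[c, :, j], lw=0.6)
        axes[0].set_title(f"trace: {name}")
        grid, dens = report.density[name]
        axes[1].plot(grid, dens)
        axes[1].set_title("density")
        lag = min(max_lag, samples.n_stored - 1)
        acf = autocorrelation(samples.draws[0, :, j], lag)
        axes[2].bar(acf.lags, acf.values, width=0.8)
        axes[2].set_title("autocorrelation")
        fig.tight_layout()
        safe = name.replace("<", "lt").replace(">=", "ge").replace("-", "_")
        path = out_dir / f"diag_{safe}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        paths.append(path)
    return paths
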