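"""Static chart export for scenario results."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402

from .scenarios import ScenarioResult, summarize_at_fraction  # noqa: E402

__all__ = ["plot_disparity_curves", "plot_component_changes"]

_COMPONENT_ORDER = ("E", "XF_bar", "D_R", "D_A")
_COMPONENT_TEX = {"E": "$E$", "XF_bar": r"$\overline{XF}$",
                  "D_R": "$D_R$", "D_A": "$D_A$"}


def plot_disparity_curves(results: dict[str, ScenarioResult], group: str,
                          path: str | Path) -> None:
    """Absolute disparity versus emission fraction reduced, one line per
    scenario."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for name, result in results.items():
        ax.plot(result.emission_fraction_reduced * 100.0,
                result.component_series(group, "D_A"), label=name)
    ax.set_xlabel("Emissions reduced (%)")
    ax.set_ylabel(f"Absolute disparity $D_A$ ({group})")
    ax.axhline(0.0, color="0.6", lw=0.8)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_component_changes(result: ScenarioResult, group: str, fraction: float,
                           path: str | Path) -> None:
    """Bar chart of the percent change in each framework component at the
    step where ``fraction`` of emissions has been removed."""
    changes = summarize_at_fraction(result, fraction)[group]
    fig, ax = plt.subplots(figsize=(5, 4))
    labels = [_COMPONENT_TEX[c] for c in _COMPONENT_ORDER]
    values = [changes[c] for c in _COMPONENT_ORDER]
    ax.bar(labels, values, color="#4878a8")
    ax.axhline(0.0, color="0.3", lw=0.8)
    ax.set_ylabel(f"Change at {fraction:.0%} emission reduction (%)")
    ax.set_title(f"{result.spec_ref.name} — group {group}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
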