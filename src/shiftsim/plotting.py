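"""Optional figure helpers (matplotlib imported lazily)."""

from __future__ import annotations

from pathlib import Path


def _plt():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_sweep(result, path: str | Path, second=None) -> None:
    """Plot one sweep (mean ± SD error bars); overlay a second curve.

    With ``second`` given (a matched-grid sweep under the other
    policy), both curves are drawn without error bars for clarity.
    """
    plt = _plt()
    fig, ax = plt.subplots(figsize=(5, 3.5))
    x = result.condition_values
    if second is None:
        ax.errorbar(x, result.mean_ratio, yerr=result.sd_ratio, fmt="o-", capsize=2)
    else:
        ax.plot(x, result.mean_ratio, "o-", color="tab:blue", label=result.policy.kind)
        ax.plot(second.condition_values, second.mean_ratio, "s-", color="tab:red",
                label=second.policy.kind)
        ax.legend()
    xlabel = {
        "load_fraction": "load (fraction of maximum strength)",
        "strength_multiplier": "maximum strength (multiple of reference)",
    }.get(result.condition_name, result.condition_name)
    ax.set_xlabel(xlabel)
    ax.set_ylabel("mean MU relaxation/contraction ratio")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_chronicity(traj, path: str | Path) -> None:
    """Three-curve trajectory: strength, threshold load, applied load."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax.plot(traj.time, traj.strength, color="tab:green", label="muscle strength")
    ax.plot(traj.time, traj.threshold_load, color="tab:red",
            label="energy-crisis threshold load")
    ax.plot(traj.time, traj.applied_load, color="tab:blue", lw=0.8,
            label="applied load")
    ep = traj.episode_flags
    ax.plot(traj.time[ep], traj.applied_load[ep], "v", color="black", ms=4,
            label="pain episode")
    ax.set_xlabel("time (arbitrary units)")
    ax.set_ylabel("force (arbitrary units)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
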