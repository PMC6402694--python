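"""Trial-to-trial variability of the delay-period neural state.

Decomposes each trial's in-plane deviation from its condition mean into
on-axis (distance) and off-axis (direction) components, compares their
magnitudes (Welch test, per task), fits 95% equal-frequency ellipses,
profiles relative deviation against reach distance, and correlates neural
deviations with kinematic deviations of the max-speed position.
"""

import json
from pathlib import Path

import numpy as np

from delaystate import core_io, subspace, variability

ROOT = Path(__file__).resolve().parents[1] / "results"
DATA = Path(__file__).resolve().parents[1] / "scratch" / "data"


def main() -> None:
    pooled = core_io.read_trials(DATA / "trials_pooled_centered.csv")
    model = subspace.SubspaceModel.from_json(DATA / "subspace_model.json")
    states = subspace.project_states(pooled, model)
    devs = variability.decompose_deviations(states)
    report = {}

    for task in devs["task"].unique():
        sub = devs[devs["task"] == task]
        t, p = variability.welch_ttest(np.abs(sub["on_axis"]), np.abs(sub["off_axis"]))
        report[f"welch_on_vs_off_{task}"] = {"t": t, "p": p}
        print(f"{task}: |on| > |off| deviations, Welch t = {t:.1f}, p = {p:.2g}")

    r3 = states[states["task"] == "rings3"]
    ellipses, scale = variability.equal_frequency_ellipses(r3, coverage=0.95)
    ratios = [e.major_length / e.minor_length for e in ellipses]
    radial = np.mean([e.orientation_rad < np.radians(15) for e in ellipses])
    report["ellipse"] = {
        "scale": scale,
        "mean_axis_ratio": float(np.mean(ratios)),
        "fraction_radially_oriented": float(radial),
    }
    print(
        f"equal-frequency ellipses: mean axis ratio {np.mean(ratios):.2f}, "
        f"{100 * radial:.0f}% oriented within 15 deg of radial"
    )

    prof = variability.relative_deviation_profile(
        devs[devs["task"].isin(["horizontal", "vertical"])]
    )
    report["relative_deviation"] = {
        "profile": prof.to_dict(orient="list"),
        "spearman": {k: {"rho": v[0], "p": v[1]} for k, v in prof.attrs["spearman"].items()},
    }
    rho, p = prof.attrs["spearman"]["on"]
    print(f"relative on-axis deviation vs distance: Spearman rho = {rho:.2f} (p = {p:.2g})")

    kin = variability.kinematic_deviations(pooled)
    corr = variability.correlate_neural_kinematic(devs, kin)
    report["neural_kinematic"] = {k: {"r": v[0], "p": v[1]} for k, v in corr.items()}
    print(
        "neural-kinematic deviation correlation: "
        f"on r = {corr['on'][0]:.2f}, off r = {corr['off'][0]:.2f}"
    )

    (ROOT / "variability_report.json").write_text(
        json.dumps(report, indent=2, default=float) + "\n"
    )


if __name__ == "__main__":
    main()
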