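"""Simulate the study's datasets: four center-out target layouts.

Writes one trial table per layout (CSV) plus a noiseless rate time-course
(HDF5) used later for convergence timing, under results/data/.
"""

from pathlib import Path

from delaystate import core_io, synthetic

SEED = 1
N_PER_CONDITION = 50
OUT = Path(__file__).resolve().parents[1] / "scratch" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    params = synthetic.GeneratorParams()
    for i, name in enumerate(("ring", "horizontal", "vertical", "rings3")):
        layout = synthetic.make_target_layout(name, "J")
        table = synthetic.simulate_trials(
            layout, params, N_PER_CONDITION, seed=SEED * 10 + i, session_id=f"s{i}"
        )
        path = core_io.write_trials(table, OUT / f"trials_{name}.csv")
        print(f"{name}: {len(table)} trials over {layout.n_conditions} conditions -> {path.name}")

    noiseless = synthetic.GeneratorParams(
        sigma_ch=0.0, sigma_speed=0.0, c_on=0.0, c_off=0.0, sigma_kin=0.0
    )
    ts = synthetic.simulate_timecourse(
        synthetic.make_target_layout("rings3", "J"),
        noiseless,
        n_per_condition=1,
        timesteps=801,
        dt=1.0,
        seed=SEED,
    )
    core_io.write_timecourse(ts, OUT / "timecourse_rings3.h5")
    print(f"time course: {ts.n_trials} trials x {ts.rates.shape[2]} ms -> timecourse_rings3.h5")


if __name__ == "__main__":
    main()
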