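"""Full conformational-landscape pipeline on the two study conditions.

Generates synthetic activation-loop feature trajectories for a wild-type-
like system (loop-down dominant, slow exchange through an intermediate)
and a tau-mutant-like system (loop-up dominant, faster direct exchange),
runs tICA -> k-means -> reversible MSM -> PCCA+ on each, and prints the
recovered equilibrium populations and mean first passage times next to the
generator's ground truth.  Numbers within a few percent of the ground
truth indicate the chain of estimators is working end to end.
"""

import numpy as np

from loopdyn.pipeline import PipelineConfig, run_pipeline

for scenario in ("wt", "tau"):
    cfg = PipelineConfig(
        scenario=scenario,
        n_trajectories=3,
        n_frames=50_000,  # scaled down for a quick demonstration
        its_lags=[1, 2, 5],
        ck_factors=[1, 2],
        seed=1,
    )
    report = run_pipeline(cfg)
    gt = report["ground_truth"]
    ms = report["stages"]["metastable"]
    order = [ms["labels"].index(l) for l in gt["state_labels"]]
    print(f"\n=== scenario: {scenario} ===")
    print(f"{'state':>14s} {'pop (true)':>11s} {'pop (est)':>10s}")
    for i, lbl in enumerate(gt["state_labels"]):
        est = ms["macro_pi"][order[i]]
        print(f"{lbl:>14s} {gt['macro_pi'][i]:11.3f} {est:10.3f}")
    m_est = np.array(ms["mfpt_matrix_ns"])[np.ix_(order, order)]
    m_true = np.array(gt["mfpt_matrix_ns"])
    iu, idn = 0, 2  # labels are ordered up, intermediate, down
    print(f"MFPT up->down:  true {m_true[iu, idn]:7.1f} ns, est {m_est[iu, idn]:7.1f} ns")
    print(f"MFPT down->up:  true {m_true[idn, iu]:7.1f} ns, est {m_est[idn, iu]:7.1f} ns")
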