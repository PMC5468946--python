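"""Metabolic-task battery: synthesis checks and negative controls.

Each task closes every exchange, opens uptakes for its allowed inputs,
adds drains for its required outputs and asks FBA whether the drains can
carry flux.  Negative controls assert that something must NOT be
producible — e.g. a cell that cannot synthesise essential nutrients.
Outputs with a minimum of 0 act as permitted byproduct sinks.
"""

from adipoflux import MetabolicTask, run_suite, toy_adipocyte_network

net = toy_adipocyte_network()

tasks = [
    MetabolicTask(
        id="acetyl_coa_from_glucose",
        allowed_inputs={"glc": 10},
        required_outputs={"accoa": 1, "co2": 0},
        description="oxidative use of glucose",
    ),
    MetabolicTask(
        id="lipid_droplet_from_tag",
        allowed_inputs={"tag": 5, "pi": 10, "nh3": 10, "h": 10},
        required_outputs={"ld": 1},
        description="re-esterification of dietary lipid",
    ),
    MetabolicTask(
        id="no_lipid_from_glucose_alone",
        allowed_inputs={"glc": 10},
        required_outputs={"ld": 0.1, "co2": 0},
        expect_feasible=False,
        description="negative control: no de-novo FA synthesis in this toy",
    ),
]

report = run_suite(net, tasks)
print(report.to_frame()[["task_id", "verdict", "feasible"]].to_string(index=False))
print(f"pass={report.n_pass} fail={report.n_fail} unresolvable={report.n_unresolvable}")
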