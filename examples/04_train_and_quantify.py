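"""Miniature end-to-end run of the sequential quantification pipeline.

Uses deliberately small grids and few epochs so the whole chain --
dictionary simulation, training of the three networks, phantom synthesis,
pixelwise quantification, vial-mean statistics -- finishes in about two
minutes.  The full-scale counterpart is `cestmrf study` (or
`scripts/acceptance.py`), which uses the shipped grids and defaults.
"""

import numpy as np

from cestmrf import ParameterGrid, RunConfig, run_phantom_study

small_grids = {
    "mt": ParameterGrid({
        "f_ss": np.round(np.arange(0.02, 0.3001, 0.02), 4),
        "k_ssw": [5.0, 20.0, 40.0, 60.0, 80.0, 100.0],
        "water_t1": [1.2, 1.8, 2.4], "water_t2": [0.03, 0.075, 0.12]}),
    "rnoe": ParameterGrid({
        "f_rnoe": [0.001, 0.005, 0.009, 0.013, 0.019],
        "k_rnoe": [5.0, 20.0, 35.0, 50.0],
        "f_ss": [0.02, 0.10, 0.18, 0.30], "k_ssw": [10.0, 40.0, 100.0],
        "water_t1": [1.2, 1.8, 2.4], "water_t2": [0.03, 0.075, 0.12]}),
    "amideglu": ParameterGrid({
        "f_amide": [0.0005, 0.0009, 0.0045, 0.0081, 0.01],
        "k_amide": [50.0, 150.0, 300.0, 500.0],
        "glu_concentration": [2.0, 5.0, 15.0, 25.0, 30.0],
        "k_glu": [4000.0, 7000.0, 10000.0],
        "f_ss": [0.02, 0.16, 0.30], "k_ssw": [10.0, 40.0, 100.0],
        "water_t1": [1.2, 1.8, 2.4], "water_t2": [0.03, 0.075, 0.12]}),
}

result = run_phantom_study(RunConfig(max_epochs=25, grids=small_grids))

table = result.report.table
print(table[["parameter", "scope", "n", "pearson_r", "icc", "bias", "rmse"]]
      .to_string(index=False))
print()
print("Reading the table: 'all' pools the 100 vials; 'bgK' is one MT")
print("background (25 vials). r measures linear agreement with the truth,")
print("ICC(2,1) additionally penalizes absolute offset and scale error.")
print("At this miniature training scale the correlations are already high")
print("for MT and amide but the absolute agreement (ICC) is visibly shrunk;")
print("the full-scale defaults (cestmrf study) recover both with ICC > 0.95.")
print("Glutamate stays strongly shrunken at any scale under this noise --")
print("it is the most noise-sensitive compound in the pipeline.")
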