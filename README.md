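# cestmrf

Multi-metabolite chemical exchange saturation transfer (CEST) MR
fingerprinting at desk scale: a multi-pool Bloch-McConnell simulator, MRF
dictionary and digital-phantom generators, a sequential neural-network
quantification pipeline, and the conventional Z-spectrum metric suite used
to benchmark it.

## The problem

CEST MRI detects dilute labile-proton pools — backbone amide protons
(+3.5 ppm), glutamate amine protons (+3 ppm), aliphatic rNOE protons
(-3.5 ppm), semisolid macromolecules — through the water signal after
chemical exchange.  The weighted contrast `MTR = 1 - S_sat/S0` mixes
concentration, exchange rate, relaxation and sequence parameters.
Fingerprinting resolves the mixture: four rapid pseudo-random saturation
protocols encode each pool into a 31-point signal trajectory, and networks
trained on simulated dictionaries decode, per pixel, the eight quantitative
parameters — volume fractions and exchange rates `(f_ss, k_ssw)`,
`(f_rnoe, k_rnoe)`, `(f_amide, k_amide)`, and the glutamate concentration
with its amine exchange rate.

The decoding is sequential: the semisolid MT network runs first (its pool
shapes the whole Z-spectrum), and its outputs feed, together with separately
measured water T1/T2 maps, the rNOE network and a combined amide/glutamate
network that resolves the +3.5 / +3 ppm spectral overlap jointly.

The package is aimed at people developing or validating saturation-transfer
quantification: everything a validation study needs — tissue models,
protocols, dictionaries, noisy digital phantoms with exact ground truth,
training, inference, recovery statistics — is generated in-repo, and the
conventional metrics (MTR, MTR_asym, MTR_Rex, AREX, dST, GluCEST, AACID,
WASSR B0 correction) are implemented for comparison against the
fingerprinting estimates.

## Worked example

```python
from cestmrf import (base_tissue, simulate_zspectrum, zspectrum_protocol,
                     mtr, mtr_asym)

tissue = base_tissue(solutes=("rnoe", "amide", "glu"))   # brain-like, 7 T
z = simulate_zspectrum(tissue, zspectrum_protocol(b1_uT=0.7, sat_duration=3.0))
print(f"Z(3.5 ppm)        = {z.interpolate(3.5):.4f}")
print(f"MTR(3.5 ppm)      = {mtr(z, 3.5):.4f}")
print(f"MTR_asym(3.5 ppm) = {mtr_asym(z, 3.5):+.4f}")
```

prints

```
Z(3.5 ppm)        = 0.5965
MTR(3.5 ppm)      = 0.4035
MTR_asym(3.5 ppm) = +0.1070
```

— 40% of the water signal is lost at the amide frequency under 0.7 uT
saturation, but only a quarter of that loss shows up in the asymmetry:
direct water saturation and the broad semisolid pool consume the rest, and
the upfield rNOE contribution partially cancels the amide and glutamate
effects it is compared against.  That entanglement is the ambiguity the
quantitative decoding resolves.  The scripts in
`examples/` walk through each capability (spectrum simulation, dictionary
encoding, phantom synthesis, training + quantification, Z-spectrum
analysis, recovery statistics); `examples/04_train_and_quantify.py` runs a
miniature version of the full pipeline in about two minutes.

The same workflow is available from the shell:

```bash
cestmrf phantom --sigma 0.01 --seed 0 --out phantom/
cestmrf dictgen --grid mt --schedule mt --out dict_mt.h5
cestmrf train --dict mt=dict_mt.h5 --net mt --out model_mt.npz
cestmrf study --out results_study/          # full experiment + report
```

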