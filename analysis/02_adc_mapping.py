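#!/usr/bin/env python
"""ADC mapping accuracy: planted vs recovered ADC, noiseless and noisy.

Writes results/adc_accuracy.csv comparing the two-point and log-linear
estimators against the planted ADC field inside the lesion.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from petmr_habitats import PhantomSpec, compute_adc_loglinear, compute_adc_two_point, generate_phantom
from petmr_habitats.synthetic import HabitatSphere

ROOT = Path(__file__).resolve().parents[1]


def spec_with_noise(sd: float) -> PhantomSpec:
    c = (48.0,) * 3
    return PhantomSpec(
        habitats=(
            HabitatSphere("outer", c, 14.0, 2.0, 1.6, dwi_noise_sd=sd),
            HabitatSphere("core", c, 8.0, 5.0, 0.9, dwi_noise_sd=sd),
        ),
        seed=42,
    )


def main() -> None:
    rows = []
    for sd in (0.0, 5.0, 15.0):
        p = generate_phantom(spec_with_noise(sd))
        inside = p.lesion_mask_mri.data
        for mode, fn in (("loglinear", compute_adc_loglinear), ("twopoint", compute_adc_two_point)):
            est = fn(p.dwi)
            err = est.data[inside] - p.adc_true.data[inside]
            rows.append(
                {
                    "dwi_noise_sd": sd,
                    "mode": mode,
                    "bias": float(err.mean()),
                    "rmse": float(np.sqrt((err**2).mean())),
                    "max_abs_err": float(np.abs(err).max()),
                    "invalid_voxels": int((~est.valid[inside]).sum()),
                }
            )
    table = pd.DataFrame(rows)
    table.to_csv(ROOT / "results" / "adc_accuracy.csv", index=False)
    print("ADC recovery inside the lesion (units 1e-3 mm^2/s):")
    print(table.to_string(index=False))
    noiseless = table[table.dwi_noise_sd == 0.0]
    assert (noiseless.max_abs_err < 1e-10).all()
    print("\nnoiseless recovery is exact to floating tolerance; "
          "log-linear is the default (uses all three b-values).")


if __name__ == "__main__":
    main()
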