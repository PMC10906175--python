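"""Ogden coefficient fitting on synthetic biaxial data.

The published biaxial dataset behind the tissue card is not deposited, so the
fitting machinery is exercised on synthetic data generated from the built-in
third-order card: noiseless uniaxial + equibiaxial stretch/stress records on
a 1.0-1.3 stretch grid, plus a 2%-multiplicative-noise replicate set.  The
fitted card must reproduce the response curves (coefficient sets themselves
are non-unique).

Writes results/material_fit.json and results/fit_curves.csv.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from laasnap import ogden

RESULTS = Path(__file__).resolve().parents[1] / "results"


def synthetic_dataset(mat, n=16, noise=0.0, rng=None):
    lam = np.linspace(1.0, 1.3, n)
    stretch = np.concatenate([lam, lam])
    stress = np.concatenate([ogden.uniaxial_nominal_stress(mat, lam),
                             ogden.equibiaxial_nominal_stress(mat, lam)])
    if noise > 0.0:
        stress = stress * (1.0 + noise * rng.standard_normal(stress.shape))
    return ogden.BiaxialDataset(tuple(["uniaxial"] * n + ["equibiaxial"] * n),
                                stretch, stress)


def response_error(fit, ref):
    # sup-norm deviation relative to the response scale over 1.0-1.3
    lam = np.linspace(1.0, 1.3, 60)
    errs = []
    for f in (ogden.uniaxial_nominal_stress, ogden.equibiaxial_nominal_stress):
        r = f(ref, lam)
        errs.append(float(np.max(np.abs(f(fit, lam) - r)) / np.max(np.abs(r))))
    return max(errs)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    RESULTS.mkdir(exist_ok=True)
    ref = ogden.table1()
    mods = ogden.initial_moduli(ref)
    print(f"reference card: mu0 = {ref.mu0:.6g} MPa, K0 = {mods['K0']:.6g} "
          f"MPa, c_d = {mods['c_d'] / 1e3:.3g} m/s")
    D1 = ogden.bulk_coeffs_from_poisson(ref.mu, ref.alpha, ref.poisson)[0]
    print(f"D1 from mu_i and nu = {ref.poisson}: {D1:.9f} 1/MPa "
          f"(card value {ref.D[0]:.9f}, rel diff "
          f"{abs(D1 - ref.D[0]) / ref.D[0]:.2e})")

    fit, diag = ogden.fit_ogden(synthetic_dataset(ref), seed=args.seed)
    err0 = response_error(fit, ref)
    print(f"noiseless fit: max response error {err0:.3e} "
          f"(residual {diag.residual_norm:.3e})")

    rng = np.random.default_rng(args.seed)
    noisy_errs = []
    for rep in range(10):
        data = synthetic_dataset(ref, noise=0.02, rng=rng)
        f_n, _ = ogden.fit_ogden(data, seed=args.seed + rep)
        noisy_errs.append(response_error(f_n, ref))
    print(f"2% noise, 10 replicates: response error median "
          f"{np.median(noisy_errs):.3%}, max {max(noisy_errs):.3%}")

    lam = np.linspace(1.0, 1.3, 60)
    np.savetxt(RESULTS / "fit_curves.csv",
               np.column_stack([lam,
                                ogden.uniaxial_nominal_stress(ref, lam),
                                ogden.uniaxial_nominal_stress(fit, lam),
                                ogden.equibiaxial_nominal_stress(ref, lam),
                                ogden.equibiaxial_nominal_stress(fit, lam)]),
               delimiter=",", comments="", fmt="%.8g",
               header="stretch,uni_ref_MPa,uni_fit_MPa,eq_ref_MPa,eq_fit_MPa")
    with open(RESULTS / "material_fit.json", "w") as fh:
        json.dump({
            "reference": ref.to_json(), "fitted": fit.to_json(),
            "D1_from_poisson": D1,
            "noiseless_response_error": err0,
            "noisy_response_errors": noisy_errs,
            "residual_norm": diag.residual_norm,
        }, fh, indent=2)
    print(f"wrote {RESULTS / 'material_fit.json'}")


if __name__ == "__main__":
    main()
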