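#!/usr/bin/env python
"""Strict signature refitting on noisy synthetic mixtures.

Builds a synthetic 96-channel signature catalog, draws Poisson-noised
spectra from a 60/40 two-signature mixture at 5000 mutations, and
refits with both strict modes (iterative backward elimination and
exhaustive best subset), reporting how often the exact generating pair
is recovered across seeds.

Writes results/signature_refit.json.
"""

import json
from pathlib import Path

import numpy as np

from perizygote import mutational_signatures as ms

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    catalog = ms.synthetic_catalog(5, seed=17)
    truth = {"SYN1": 3000, "SYN2": 2000}
    summary = {}
    for method in ("strict", "best_subset"):
        exact = 0
        cosines = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            spectrum = ms.sample_spectrum(truth, catalog, rng)
            res = ms.strict_refit_best_subset(spectrum, catalog, method=method)
            exact += set(res.signatures) == set(truth)
            cosines.append(res.cosine)
        summary[method] = {
            "exact_recovery": exact,
            "seeds": 100,
            "mean_cosine": float(np.mean(cosines)),
        }
        print(
            f"{method}: exact two-signature recovery {exact}/100, "
            f"mean reconstruction cosine {np.mean(cosines):.4f}"
        )
    OUT.mkdir(exist_ok=True)
    with open(OUT / "signature_refit.json", "w") as fh:
        json.dump({"truth_exposures": truth, "methods": summary}, fh, indent=2)
        fh.write("\n")
    print(f"wrote {OUT / 'signature_refit.json'}")


if __name__ == "__main__":
    main()
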