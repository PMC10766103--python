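"""End-to-end demo: phantoms -> feature maps -> classifier -> metrics.

Uses a reduced study (8 training + 4 test frames per class, 6 epochs) so
it finishes in about a minute on one CPU; the test suite runs the full
40-train / 20-test version.
"""

import time

from rfbispec.experiments import synthetic_end_to_end

t0 = time.time()
study = synthetic_end_to_end(
    seed=0,
    n_train_per_class=8,
    n_test_per_class=4,
    max_epochs=6,
    run_ablation=False,
)
rep = study["full"]
print(f"trained on {study['n_train']} frames, tested on {study['n_test']}")
print(f"held-out AUC        : {rep.AUC:.3f}")
print(f"held-out accuracy   : {rep.accuracy:.2f}%")
print(f"sensitivity         : {rep.sensitivity:.2f}%")
print(f"specificity         : {rep.specificity:.2f}%")
print("attention importance:", {k: round(v, 3) for k, v in study["importance"].items()})
print(f"elapsed             : {time.time() - t0:.0f}s")

print(
    "\nAUC near 1 means the classifier recovers the class-dependent\n"
    "nonlinearity/scatterer-density signature that the phantom encodes in\n"
    "the bispectral band energies; the importance weights show which of\n"
    "the four maps the attention module leaned on.  At this reduced size\n"
    "the score ranking separates the classes before the 0.5 operating\n"
    "point calibrates, so threshold metrics can lag the AUC — the full\n"
    "40/20 study in the test suite reaches high accuracy as well."
)
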