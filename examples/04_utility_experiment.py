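"""Does pseudonymization harm downstream performance?

Runs the full utility protocol on a synthetic document-classification task
whose label signal lives in non-PII tokens: fine-tune the lightweight
classifier on the original and on a pseudonymized version of the corpus with
fold-matched 10-fold cross-validation, then compare every ordered pair of
configurations with a one-sided Mann-Whitney U test.
"""

import logging

from pseudoclin import RunConfig, run_end_to_end

# the degraded "pseudo" detector intentionally produces spurious spans whose
# text no rule can parse; silence the resulting passthrough warnings
logging.getLogger("pseudoclin.surrogate").setLevel(logging.ERROR)

config = RunConfig(
    out_dir="scratch/utility-demo",
    master_seed=17,
    n_notes=200,
    n_task_docs=200,
    k=10,
    models=["tf-nb"],
    detectors={"pseudo": (0.1, 0.5), "pseudo+": (0.0, 0.0)},
)
manifest = run_end_to_end(config)

print("stages:", ", ".join(manifest["stages"]))
print("note corpus PII density:", manifest["pii_density_pct"], "%")
print("configurations:", manifest["n_configurations"],
      "| cross-validation runs:", manifest["n_runs"])
print("pairwise one-sided tests:", manifest["n_comparisons"],
      "| significant at 0.05:", manifest["n_significant"])
print()
print("With the signal outside PII, pseudonymized and original training data "
      "should be statistically indistinguishable: expect zero or chance-level "
      "significant comparisons. Scores and test results are written under",
      config.out_dir)
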