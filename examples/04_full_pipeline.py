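"""The whole analysis in one call, on a synthetic study.

generate_study emulates the experimental design (6 symbiotypes x 30
females, mating failures and exclusions included); run_pipeline chains
exclusions -> baseline mortality -> equilibrium expectations -> Monte
Carlo CIs -> overdispersion-corrected statistics and returns one
JSON-serialisable document. Equivalent shell command:

    femcost run-all --draws 500000 --seed 11 --out results.json
"""

import femcost as fc
from femcost.io import write_results

table = fc.generate_study(fc.StudyDesign(), fc.GeneratorParams(seed=11))
doc = fc.run_pipeline(table, fc.PipelineConfig(n_draws=100_000, seed=11))

print(f"broods analysed: {doc['n_broods']}, "
      f"baseline failure rate b = {doc['baseline_b']:.4f}")
for s, entry in doc["symbiotypes"].items():
    print(f"{s:8s} expected = {entry['expected_undeveloped']:.3f}  "
          f"observed = {entry['observed_mean_undeveloped']:.3f}  "
          f"CI = [{entry['ci_lo']:.3f}, {entry['ci_hi']:.3f}]  "
          f"within CI: {entry['observed_within_ci']}")
print("  -> an observed mean inside its CI means inviable 00 eggs alone\n"
      "     suffice to explain that symbiotype's egg-development deficit")

st = doc["stats"]
print(f"\ndDeviance (6 symbiotypes) = {st['delta_deviance_symbiotype']:.2f} "
      f"on {st['df_symbiotype']} df, p = {st['p_symbiotype']:.2e}")
print(f"egg reduction in feminized lines: {st['egg_reduction_percent']:.1f}%")
print(f"Tukey letters on total eggs: {st['tukey_letters']}")
print("\nfull document (also what `femcost run-all` writes):")
print(write_results(doc, None)[:200] + " ...")
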