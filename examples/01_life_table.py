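"""Build a cohort life table from stranded-dolphin ages at death.

Simulates a stranding record the size of a typical multi-decade monitoring
program (220 aged natural deaths), treats it as a synthetic cohort, and
prints the life-table columns: survivorship l(x), annual death probability
q(x), and remaining life expectancy e(x).
"""
import strandmort as sm

sample = sm.simulate_natural(sm.ScenarioSpec(n_bycatch=0, seed=1))
table = sm.build_life_table(sample)

print(table.to_frame().round(3).to_string(index=False))
print(f"\n{len(sample)} strandings; life expectancy at birth "
      f"e(0) = {table.e[0]:.1f} yr; half the cohort is gone by the first "
      "age where l(x) < 0.5.")
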