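"""Run the complete two-state stability design on one synthetic protein.

Generates a fixture bundle (paired structures, MSA, per-state ddG tables
with planted sign classes), runs the workflow and prints the Table-1-style
summary: per tier the chosen energy cutoff, mutation count and mutational
load. X.3 drops every mutation whose ddG is not negative in both states;
X.4 additionally avoids the hinge and lobe interface at X.3's cutoff.
"""

from twostate import FixtureSpec, make_fixture_bundle, run_workflow

bundle = make_fixture_bundle(FixtureSpec(n_per_lobe=30, seed=5))
result = run_workflow(
    bundle.pair,
    msa=bundle.msa,
    ddg_open_tsv=bundle.ddg.open_tsv,
    ddg_closed_tsv=bundle.ddg.closed_tsv,
)

print(f"{'tier':>5s} {'cutoff':>7s} {'n_mut':>5s} {'load%':>6s}  mutations")
for tier in ("X.0", "X.1", "X.2", "X.3", "X.4"):
    v = result.variants[tier]
    cut = "-" if tier == "X.0" else f"{v.cutoff:.2f}"
    muts = " ".join(str(m) for m in v.mutations) or "-"
    print(f"{tier:>5s} {cut:>7s} {v.n_mutations:5d} {v.mutational_load:6.1f}  {muts}")

n_discordant = sum(
    1 for r in result.records if (r.ddg_open < 0) != (r.ddg_closed < 0)
)
print(f"\nsign-discordant candidates removed by the two-state filter: "
      f"{n_discordant} of {len(result.records)}")
print("X.4 is a subset of X.3 at the same cutoff: the difference is exactly "
      "the mutations sitting on the hinge or lobe interface.")
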