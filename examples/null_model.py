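"""How much repeated evolution is expected by chance alone?

Places S = 667 substitution events uniformly over the variable sites of a
5386-nt genome (25% of sites assumed invariant) and prints the expected
number of sites hit n times.  Observed repeated evolution far above these
expectations is the signature of adaptive substitution.
"""

from paraphage import (
    NullModelParams,
    null_table,
    poisson_occupancy_expectation,
)

params = NullModelParams(S=667, G=5386, f=0.25)
print(f"S = {params.S} events over L = {params.L} variable sites "
      f"(lambda = {params.event_density:.3f} events/site)\n")

df = null_table(params, n_max=5).to_frame()
df["poisson_occupancy"] = [
    poisson_occupancy_expectation(params, int(n)) for n in df["n"]
]
print(df.to_string(index=False, float_format=lambda x: f"{x:.2f}"))

print(
    "\nReading: ~55 sites are expected to be hit twice by chance (16% of all"
    "\nevents), but only ~3 sites thrice - so three or more events at one"
    "\nsite is strong evidence of adaptation.  The last column shows the"
    "\nPoisson >=n-site occupancy alternative for comparison."
)
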