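"""Clone-envelope analytics and the degenerate simulator limit.

A founding mother with mean lifespan L whose clone doubles every generation
reaches 2^L cells unselected; under 5-FOA counter-selection the clone is
halted at the silencing-loss generation, at the earliest ceil(0.7*L).  In the
dispersion-free limit (cv=0, loss window [1,1]) the cohort simulator must
reproduce the closed form exactly.
"""

from silencescreen import Library, PoolState, StrainSpec, clone_envelope

print("30-generation founder, no 5-FOA:       ", clone_envelope(30, foa_on=False))
print("30-generation founder, 5-FOA, 70% loss:", clone_envelope(30, foa_on=True, loss_fraction=0.7))

print("\ndegenerate-limit simulator vs closed form:")
for L in (1, 5, 12, 30):
    lib = Library((StrainSpec("A", float(L), 0.0, 1.0, 1.0),))
    st = PoolState.initialize(lib, 1.0, foa_on=False)
    for _ in range(L):
        st.step()
    print(f"  L={L:>2}: simulated {st.total():>12.0f}  closed form {clone_envelope(L, False):>12}")

# The two printed columns agree exactly: the age-structured cohort recursion
# collapses to pure doubling when every mother lives exactly L divisions.
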