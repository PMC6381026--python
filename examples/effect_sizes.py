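"""Compute CE-FDH necessity and sufficiency effect sizes on a small scatter.

Uses the packaged 12-point worked example (X on a 3-level scale, Y on 1..10)
and prints the empty-corner areas, the scope, and the benchmark labels.
"""

from ncaperm import load_worked_example, necessity_effect, sufficiency_effect

observed, _ = load_worked_example()

nec = necessity_effect(observed)
suf = sufficiency_effect(observed)
print(nec)
print(suf)

# The necessity effect is the share of the scope rectangle that is empty
# above the ceiling step (upper-left corner): 3 of 18 units here, a
# "medium" effect.  The sufficiency effect is the mirror share below the
# floor step (lower-right corner).
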