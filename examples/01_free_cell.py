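"""Free relaxation-oscillator cell: period, duty cycle, nullcline knees.

A single uncoupled cell with the default constants settles onto a limit
cycle that spends almost the whole period on the silent (left) branch of the
cubic V-nullcline and only a short burst on the active (right) branch.
"""
from gapring import CellParams, free_cycle, v_nullcline

cell = CellParams()
cyc = free_cycle(cell)
curve = v_nullcline(0.0, cell)

print(f"period T            : {cyc['T']:.1f} time units")
print(f"duty cycle dt/T     : {cyc['duty'] * 100:.2f} %")
print(f"left knee  (V, W)   : ({curve.left_knee[0]:+.3f}, "
      f"{curve.left_knee[1]:+.3f})")
print(f"right knee (V, W)   : ({curve.right_knee[0]:+.3f}, "
      f"{curve.right_knee[1]:+.3f})")
print()
print("The duty cycle of 1-2 % is what lets many phase groups fit into one")
print("cycle; the knees are where jumps between silent and active phase "
      "start.")
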