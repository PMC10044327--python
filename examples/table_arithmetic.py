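"""Reproduce the mean +- SE aggregation of a published evaluation table row.

Given the three per-axis %RMSE values of a force group, `aggregate_group`
returns the arithmetic mean and the standard error (n-1 SD over the three
axes / sqrt(3)); `accuracy_from_rmse` converts the mean error into the
estimation accuracy.
"""

from grfest import accuracy_from_rmse, aggregate_group

# per-axis force errors of the best below-knee sensor combination (sway task)
fx, fy, fz = 8.00, 10.0, 6.67
mean, se = aggregate_group((fx, fy, fz))
print(f"Fx {fx} %, Fy {fy} %, Fz {fz} %")
print(f"group summary : {mean:.2f} % +- {se:.2f} % (mean +- SE)")
print(f"accuracy      : {accuracy_from_rmse(mean):.2f} %")

# all-IMU combination for comparison
mean2, se2 = aggregate_group((7.83, 9.00, 6.67))
print(f"\nall-IMU combination: {mean2:.2f} % +- {se2:.2f} %")
print(f"error reduction vs all-EMG (9.94 %): {9.94 - mean2:.2f} points")
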