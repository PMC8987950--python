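"""Reported statistics from the motivating study, used as fixed inputs.

``REPORTED_OMNIBUS`` holds the omnibus test statistics printed for the
three-game × four-height comparison (F, df1, df2, partial η² as printed);
only the rows whose η² is arithmetically consistent with the printed F and
dfs are listed.  ``REPORTED_VELOCITY_MEANS`` holds the reported peak
lumbar-velocity condition means (deg/s) for (dodgeball game, fish game) at
the highest and lowest intended impact heights.
"""

# name: (F, df1, df2, printed partial eta squared)
REPORTED_OMNIBUS = {
    "lumbar_velocity_game": (17.002, 2, 48, 0.415),
    "lumbar_motion_game": (2.739, 2, 48, 0.102),
    "lumbar_motion_interaction": (22.092, 2.9, 69.7, 0.479),
    "impact_ap_height": (29.704, 3, 72, 0.553),
    "impact_vertical_interaction": (150.701, 3.8, 91.0, 0.863),
    "impact_vertical_game": (16.653, 1.6, 37.8, 0.41),
}

# (dodgeball mean, fish mean) in deg/s
REPORTED_VELOCITY_MEANS = {
    "height1": (71.5, 44.3),
    "height4": (88.7, 70.2),
}
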