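"""Frozen reference values for the benchmark grids.

Keys of the outer dicts are the compound weight lambda1 (0.25, 0.5,
0.75) or the string "DA"; rows index the variance settings (1,1,1),
(1,2,3), (1,2,4); columns index the cost settings (10,20,20),
(10,20,30), (10,20,40).  All grids use budget 50,000, overhead 100 and
pairwise correlations 0.5.
"""

# scenario 1 optima: (N01, N02, N_total)
SCENARIO1_OPTIMA = {
    0.25: [
        [(141, 243, 384), (138, 229, 367), (133, 218, 351)],
        [(123, 261, 384), (124, 242, 366), (118, 231, 349)],
        [(111, 273, 384), (110, 255, 365), (103, 244, 347)],
    ],
    0.5: [
        [(192, 192, 384), (194, 177, 371), (185, 173, 358)],
        [(173, 211, 384), (166, 203, 369), (170, 186, 356)],
        [(159, 225, 384), (152, 216, 368), (155, 199, 354)],
    ],
    0.75: [
        [(243, 141, 384), (237, 137, 374), (238, 127, 365)],
        [(225, 159, 384), (222, 151, 373), (215, 147, 362)],
        [(211, 173, 384), (208, 164, 372), (208, 153, 361)],
    ],
    "DA": [
        [(192, 192, 384), (194, 177, 371), (193, 166, 359)],
        [(190, 194, 384), (194, 177, 371), (193, 166, 359)],
        [(189, 195, 384), (194, 177, 371), (185, 173, 358)],
    ],
}

# scenario 2 optima: (N01, N02, N12, N_total)
SCENARIO2_OPTIMA = {
    0.25: [
        [(119, 229, 34, 382), (116, 213, 34, 363), (117, 201, 29, 347)],
        [(54, 210, 112, 376), (57, 196, 101, 354), (64, 184, 88, 336)],
        [(34, 216, 125, 375), (39, 202, 111, 352), (41, 189, 102, 332)],
    ],
    0.5: [
        [(167, 167, 47, 381), (172, 161, 34, 367), (171, 151, 32, 354)],
        [(111, 153, 112, 376), (113, 144, 101, 358), (113, 133, 96, 342)],
        [(89, 161, 125, 375), (94, 152, 110, 356), (94, 142, 103, 339)],
    ],
    0.75: [
        [(229, 119, 34, 382), (227, 111, 33, 371), (224, 104, 33, 361)],
        [(178, 100, 99, 377), (177, 91, 95, 363), (177, 85, 89, 351)],
        [(157, 107, 112, 376), (158, 99, 104, 361), (158, 94, 96, 348)],
    ],
    "DA": [
        [(132, 132, 112, 376), (140, 120, 100, 360), (147, 111, 89, 347)],
        [(99, 109, 164, 372), (107, 96, 151, 354), (118, 86, 136, 340)],
        [(98, 110, 164, 372), (108, 94, 152, 354), (113, 85, 141, 339)],
    ],
}

# uniform-allocation efficiencies: (RE scenario 1, RE scenario 2), 3 dp
UNIFORM_EFFICIENCIES = {
    0.25: [
        [(0.943, 0.877), (0.951, 0.878), (0.957, 0.875)],
        [(0.887, 0.900), (0.898, 0.911), (0.906, 0.916)],
        [(0.851, 0.871), (0.863, 0.885), (0.873, 0.893)],
    ],
    0.5: [
        [(1.000, 0.928), (0.999, 0.920), (0.995, 0.908)],
        [(0.990, 0.991), (0.993, 0.993), (0.993, 0.988)],
        [(0.972, 0.978), (0.977, 0.984), (0.979, 0.983)],
    ],
    0.75: [
        [(0.943, 0.877), (0.933, 0.860), (0.920, 0.840)],
        [(0.972, 0.969), (0.965, 0.958), (0.956, 0.944)],
        [(0.990, 0.987), (0.985, 0.981), (0.979, 0.968)],
    ],
    "DA": [
        [(1.000, 0.999), (0.998, 0.996), (0.994, 0.986)],
        [(1.000, 0.990), (0.999, 0.992), (0.995, 0.987)],
        [(1.000, 0.987), (0.999, 0.990), (0.995, 0.986)],
    ],
}

# incomplete-vs-complete efficiencies: (RE scenario 1, RE scenario 2), 3 dp
COMPLETE_EFFICIENCIES = {
    0.25: [
        [(0.699, 0.713), (0.713, 0.724), (0.723, 0.732)],
        [(0.656, 0.734), (0.666, 0.736), (0.674, 0.738)],
        [(0.681, 0.776), (0.690, 0.776), (0.697, 0.776)],
    ],
    0.5: [
        [(0.659, 0.674), (0.678, 0.691), (0.695, 0.706)],
        [(0.590, 0.662), (0.605, 0.671), (0.618, 0.679)],
        [(0.599, 0.683), (0.613, 0.690), (0.624, 0.696)],
    ],
    0.75: [
        [(0.699, 0.713), (0.727, 0.739), (0.752, 0.763)],
        [(0.605, 0.671), (0.627, 0.689), (0.646, 0.705)],
        [(0.592, 0.666), (0.612, 0.682), (0.629, 0.695)],
    ],
    "DA": [
        [(0.577, 0.627), (0.594, 0.639), (0.609, 0.650)],
        [(0.550, 0.654), (0.566, 0.663), (0.580, 0.671)],
        [(0.553, 0.664), (0.569, 0.673), (0.583, 0.681)],
    ],
}

# complete-design sizes per cost setting
COMPLETE_SIZES = (333, 312, 294)
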