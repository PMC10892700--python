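{
  "_comment": [
    "Published RULA worksheet lookup tables (McAtamney & Corlett 1993).",
    "table_a is indexed [upper_arm 1-6][lower_arm 1-3][wrist 1-4][wrist_twist 1-2];",
    "table_b is indexed [neck 1-6][trunk 1-6][legs 1-2];",
    "table_c is indexed [score_A 1-8 (8 = 8+)][score_B 1-7 (7 = 7+)].",
    "All indices here are 0-based arrays of the 1-based worksheet scores.",
    "bins document the angle-to-partial-score cut points in degrees;",
    "intervals are closed on the score-1 (safer) side."
  ],
  "table_a": [
    [[[1,2],[2,2],[2,3],[3,3]], [[2,2],[2,2],[3,3],[3,3]], [[2,3],[3,3],[3,3],[4,4]]],
    [[[2,3],[3,3],[3,4],[4,4]], [[3,3],[3,3],[3,4],[4,4]], [[3,4],[4,4],[4,4],[5,5]]],
    [[[3,3],[4,4],[4,4],[5,5]], [[3,4],[4,4],[4,4],[5,5]], [[4,4],[4,4],[4,5],[5,5]]],
    [[[4,4],[4,4],[4,5],[5,5]], [[4,4],[4,4],[4,5],[5,5]], [[4,4],[4,5],[5,5],[6,6]]],
    [[[5,5],[5,5],[5,6],[6,7]], [[5,6],[6,6],[6,7],[7,7]], [[6,6],[6,7],[7,7],[7,8]]],
    [[[7,7],[7,7],[7,8],[8,9]], [[8,8],[8,8],[8,9],[9,9]], [[9,9],[9,9],[9,9],[9,9]]]
  ],
  "table_b": [
    [[1,3],[2,3],[3,4],[5,5],[6,6],[7,7]],
    [[2,3],[2,3],[4,5],[5,5],[6,7],[7,7]],
    [[3,3],[3,4],[4,5],[5,6],[6,7],[7,7]],
    [[5,5],[5,6],[6,7],[7,7],[7,7],[8,8]],
    [[7,7],[7,7],[7,8],[8,8],[8,8],[8,8]],
    [[8,8],[8,8],[8,8],[8,9],[9,9],[9,9]]
  ],
  "table_c": [
    [1,2,3,3,4,5,5],
    [2,2,3,4,4,5,5],
    [3,3,3,4,4,5,6],
    [3,3,3,4,5,6,6],
    [4,4,4,5,6,7,7],
    [4,4,5,6,6,7,7],
    [5,5,6,6,7,7,7],
    [5,5,6,7,7,7,7]
  ],
  "bins": {
    "upper_arm_flexion": {"score1": [-20, 20], "score2_flex": [20, 45], "score3": [45, 90], "score4_above": 90},
    "upper_arm_abducted_above_deg": 45,
    "lower_arm_flexion_score1": [60, 100],
    "wrist_flexion": {"score1_abs": 5, "score2_abs": 15},
    "wrist_deviated_above_deg": 10,
    "wrist_twist_endrange_above_deg": 45,
    "neck_flexion": {"score1": [-5, 10], "score2": [10, 20], "score3_above": 20, "score4_extension_below": -5},
    "trunk_flexion": {"score1_abs": 5, "score2": [5, 20], "score3": [20, 60], "score4_above": 60, "extension_below": -5}
  }
}
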