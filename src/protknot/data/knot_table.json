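{
  "version": 1,
  "comment": "Prime knots through 7 crossings. 'alexander' is the dense coefficient tuple of the Alexander polynomial normalized to lowest degree 0 and value +1 at t=1; 'det' is |Delta(-1)|; 'chiral' marks knots distinct from their mirror image.",
  "knots": [
    {"name": "0_1", "alexander": [1], "det": 1, "chiral": false},
    {"name": "3_1", "alexander": [1, -1, 1], "det": 3, "chiral": true},
    {"name": "4_1", "alexander": [-1, 3, -1], "det": 5, "chiral": false},
    {"name": "5_1", "alexander": [1, -1, 1, -1, 1], "det": 5, "chiral": true},
    {"name": "5_2", "alexander": [2, -3, 2], "det": 7, "chiral": true},
    {"name": "6_1", "alexander": [-2, 5, -2], "det": 9, "chiral": true},
    {"name": "6_2", "alexander": [-1, 3, -3, 3, -1], "det": 11, "chiral": true},
    {"name": "6_3", "alexander": [1, -3, 5, -3, 1], "det": 13, "chiral": false},
    {"name": "7_1", "alexander": [1, -1, 1, -1, 1, -1, 1], "det": 7, "chiral": true},
    {"name": "7_2", "alexander": [3, -5, 3], "det": 11, "chiral": true},
    {"name": "7_3", "alexander": [2, -3, 3, -3, 2], "det": 13, "chiral": true},
    {"name": "7_4", "alexander": [4, -7, 4], "det": 15, "chiral": true},
    {"name": "7_5", "alexander": [2, -4, 5, -4, 2], "det": 17, "chiral": true},
    {"name": "7_6", "alexander": [-1, 5, -7, 5, -1], "det": 19, "chiral": true},
    {"name": "7_7", "alexander": [1, -5, 9, -5, 1], "det": 21, "chiral": true}
  ]
}
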