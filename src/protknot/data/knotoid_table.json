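{
  "version": 1,
  "comment": "Reference diagrams for planar knotoids through three crossings. Each entry is a 3D polyline whose generic projection along +z realizes the reference diagram with the stated crossing number; loop brackets (and mirrors, suffix m) are computed on load and self-checked for pairwise separation. Handedness convention: k3.1 is the knotoid of the open right-handed trefoil (the torus-knot parametrization that names 3_1+).",
  "knotoids": [
    {
      "name": "k0.1",
      "crossings": 0,
      "chiral": false,
      "xyz": [[-3, 0, 0], [3, 0.3, 0]]
    },
    {
      "name": "k2.1",
      "crossings": 2,
      "chiral": true,
      "xyz": [[-3, 0, 0], [3, 0, 0], [3, 2, 0], [-1, 2, 1], [-1, -1, 1], [1, -1, -1], [1, 1, -1]]
    },
    {
      "name": "k3.1",
      "crossings": 3,
      "chiral": true,
      "xyz": [[6.73, 2.16, 0.54], [-3.37, -1.1, -1.07], [1.65, -2.28, 1.19], [1.65, 2.28, -1.19], [-1.07, -1.47, 0.19], [6.73, -2.16, -0.54]]
    },
    {
      "name": "k3.2",
      "crossings": 3,
      "chiral": true,
      "xyz": [[-0.85, 1.3, 0.78], [-1.96, -4.08, -0.37], [2.08, 1.69, -0.31], [-1.08, 1.11, 0.61], [-0.43, 1.7, 0.28], [0.33, -3.19, 1.04]]
    }
  ]
}
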