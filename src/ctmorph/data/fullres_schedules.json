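{
  "whole_body": {
    "stop_epsilon": 1e-06,
    "stages": [
      {
        "model": "rigid",
        "factors": [
          12,
          8,
          4,
          2
        ],
        "iterations": [
          1000,
          500,
          250,
          0
        ],
        "sigmas": [
          4.0,
          3.0,
          2.0,
          1.0
        ]
      },
      {
        "model": "affine",
        "factors": [
          12,
          8,
          4,
          2
        ],
        "iterations": [
          1000,
          500,
          250,
          0
        ],
        "sigmas": [
          4.0,
          3.0,
          2.0,
          1.0
        ]
      },
      {
        "model": "diffeomorphic",
        "factors": [
          12,
          8,
          4,
          2
        ],
        "iterations": [
          1000,
          500,
          250,
          0
        ],
        "sigmas": [
          4.0,
          3.0,
          2.0,
          1.0
        ]
      }
    ]
  },
  "organ": {
    "stop_epsilon": 1e-06,
    "stages": [
      {
        "model": "rigid",
        "factors": [
          12,
          8,
          4,
          2
        ],
        "iterations": [
          1000,
          500,
          250,
          100
        ],
        "sigmas": [
          4.0,
          3.0,
          2.0,
          1.0
        ]
      },
      {
        "model": "affine",
        "factors": [
          12,
          8,
          4,
          2
        ],
        "iterations": [
          1000,
          500,
          250,
          100
        ],
        "sigmas": [
          4.0,
          3.0,
          2.0,
          1.0
        ]
      },
      {
        "model": "diffeomorphic",
        "factors": [
          10,
          6,
          4,
          2,
          1
        ],
        "iterations": [
          500,
          500,
          500,
          250,
          125
        ],
        "sigmas": [
          5.0,
          3.0,
          2.0,
          1.0,
          0.0
        ]
      }
    ]
  }
}
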