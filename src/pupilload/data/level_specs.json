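{
  "levels": [
    {
      "level_id": "L1a",
      "world": "A",
      "origins": 1,
      "targets": 1,
      "two_way_splitters": 2,
      "three_way_splitters": 1,
      "pipe_bends": 3,
      "obstacles": 10,
      "total_elements": 18
    },
    {
      "level_id": "L2a",
      "world": "A",
      "origins": 1,
      "targets": 2,
      "two_way_splitters": 2,
      "three_way_splitters": 1,
      "pipe_bends": 3,
      "obstacles": 10,
      "total_elements": 19
    },
    {
      "level_id": "L3b",
      "world": "B",
      "origins": 1,
      "targets": 2,
      "two_way_splitters": 1,
      "three_way_splitters": 2,
      "pipe_bends": 3,
      "obstacles": 13,
      "total_elements": 22
    },
    {
      "level_id": "L4b",
      "world": "B",
      "origins": 3,
      "targets": 3,
      "two_way_splitters": 1,
      "three_way_splitters": 3,
      "pipe_bends": 3,
      "obstacles": 10,
      "total_elements": 23
    }
  ]
}
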