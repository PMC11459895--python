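{
  "comment": "Single-site toy worked example: schedule |AABB|ABBA| plus one spare block, initial kits (2 A, 3 B), eight sequential patients, one re-supply of (2 A, 2 B) ordered after patient 2 and delivered between patients 5 and 6.",
  "list_arms": "AABBABBAAABB",
  "block_size": 4,
  "sites": [
    {"site_id": 0, "activation_time": 0.0, "initial_A": 2, "initial_B": 3}
  ],
  "arrivals": [
    {"time": 1.0, "site_id": 0},
    {"time": 2.0, "site_id": 0},
    {"time": 3.0, "site_id": 0},
    {"time": 4.0, "site_id": 0},
    {"time": 5.0, "site_id": 0},
    {"time": 6.0, "site_id": 0},
    {"time": 7.0, "site_id": 0},
    {"time": 8.0, "site_id": 0}
  ],
  "shipments": [
    {"site_id": 0, "order_time": 2.0, "delivery_time": 5.5, "qty_A": 2, "qty_B": 2}
  ],
  "n_target": 8
}
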