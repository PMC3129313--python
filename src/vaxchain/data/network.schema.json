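{
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "title": "vaxchain supply network",
 "type": "object",
 "required": ["locations", "routes"],
 "properties": {
  "locations": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["location_id", "level", "devices"],
    "properties": {
     "location_id": {"type": "string"},
     "level": {"enum": ["central", "regional", "district", "clinic"]},
     "reorder_point_fraction": {"type": "number", "minimum": 0, "maximum": 1},
     "buffer_fraction": {"type": "number", "minimum": 0},
     "birth_share": {"type": ["number", "null"], "minimum": 0, "maximum": 1},
     "devices": {
      "type": "array",
      "items": {
       "type": "object",
       "required": ["device_id", "kind", "net_capacity"],
       "properties": {
        "device_id": {"type": "string"},
        "kind": {"enum": ["cold_room", "refrigerator", "freezer"]},
        "net_capacity": {"type": "number", "exclusiveMinimum": 0},
        "temperature_class": {"enum": ["refrigerated", "frozen", ""]}
       }
      }
     }
    }
   }
  },
  "routes": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["route_id", "origin", "stops", "transport", "trips_per_year"],
    "properties": {
     "route_id": {"type": "string"},
     "origin": {"type": "string"},
     "stops": {"type": "array", "items": {"type": "string"}, "minItems": 1},
     "trips_per_year": {"type": "number", "exclusiveMinimum": 0},
     "mode": {"enum": ["delivery", "collection"]},
     "transport": {
      "type": "object",
      "required": ["device_id", "kind", "net_capacity"],
      "properties": {
       "device_id": {"type": "string"},
       "kind": {"enum": ["cold_truck", "four_by_four", "cold_box", "vaccine_carrier"]},
       "net_capacity": {"type": "number", "exclusiveMinimum": 0},
       "loss_probability": {"type": ["number", "null"], "minimum": 0, "maximum": 1}
      }
     }
    }
   }
  }
 }
}
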