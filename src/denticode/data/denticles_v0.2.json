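{
 "version": "denticles_v0.2",
 "historical": true,
 "note": "historical, matrices unavailable",
 "traits": [],
 "nesting_rules": []
}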