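{"type": "FeatureCollection", "metadata": {"lake": "Garve", "synthetic": true, "approximate": true, "note": "constructed stand-in shoreline; coarse aspect only, area normalized on load", "crs": "planar meters, centroid origin"}, "features": [{"type": "Feature", "properties": {"role": "lake"}, "geometry": {"type": "Polygon", "coordinates": [[[1165.8, 0.0], [1155.7, 25.2], [1142.6, 50.0], [1126.9, 74.1], [1108.7, 97.6], [1088.5, 120.3], [1066.5, 142.2], [1043.0, 163.4], [1018.3, 183.8], [992.6, 203.4], [966.2, 222.4], [939.3, 240.6], [912.0, 258.2], [884.5, 275.2], [856.8, 291.7], [829.0, 307.7], [801.1, 323.4], [773.2, 338.6], [745.0, 353.5], [716.7, 368.1], [688.1, 382.3], [659.1, 396.1], [629.6, 409.5], [599.5, 422.5], [568.8, 434.9], [537.4, 446.8], [505.2, 458.0], [472.3, 468.5], [438.5, 478.1], [404.0, 486.9], [368.8, 494.7], [333.0, 501.4], [296.6, 507.1], [259.7, 511.6], [222.6, 515.1], [185.3, 517.4], [147.9, 518.7], [110.5, 518.8], [73.4, 518.0], [36.5, 516.3], [0.0, 513.8], [-36.1, 510.5], [-71.8, 506.6], [-107.0, 502.2], [-141.8, 497.4], [-176.2, 492.3], [-210.4, 486.9], [-244.4, 481.4], [-278.3, 475.9], [-312.3, 470.3], [-346.5, 464.7], [-381.0, 459.2], [-416.0, 453.6], [-451.5, 447.9], [-487.7, 442.1], [-524.5, 436.1], [-562.0, 429.8], [-600.3, 423.0], [-639.1, 415.7], [-678.4, 407.7], [-718.1, 399.0], [-758.0, 389.2], [-797.7, 378.5], [-837.1, 366.6], [-875.8, 353.5], [-913.6, 339.1], [-950.0, 323.4], [-984.8, 306.4], [-1017.5, 288.0], [-1047.9, 268.4], [-1075.6, 247.5], [-1100.4, 225.5], [-1122.0, 202.5], [-1140.1, 178.6], [-1154.8, 154.0], [-1165.7, 128.8], [-1173.0, 103.2], [-1176.5, 77.4], [-1176.4, 51.4], [-1172.8, 25.6], [-1165.8, 0.0], [-1155.7, -25.2], [-1142.6, -50.0], [-1126.9, -74.1], [-1108.7, -97.6], [-1088.5, -120.3], [-1066.5, -142.2], [-1043.0, -163.4], [-1018.3, -183.8], [-992.6, -203.4], [-966.2, -222.4], [-939.3, -240.6], [-912.0, -258.2], [-884.5, -275.2], [-856.8, -291.7], [-829.0, -307.7], [-801.1, -323.4], [-773.2, -338.6], [-745.0, -353.5], [-716.7, -368.1], [-688.1, -382.3], [-659.1, -396.1], [-629.6, -409.5], [-599.5, -422.5], [-568.8, -434.9], [-537.4, -446.8], [-505.2, -458.0], [-472.3, -468.5], [-438.5, -478.1], [-404.0, -486.9], [-368.8, -494.7], [-333.0, -501.4], [-296.6, -507.1], [-259.7, -511.6], [-222.6, -515.1], [-185.3, -517.4], [-147.9, -518.7], [-110.5, -518.8], [-73.4, -518.0], [-36.5, -516.3], [-0.0, -513.8], [36.1, -510.5], [71.8, -506.6], [107.0, -502.2], [141.8, -497.4], [176.2, -492.3], [210.4, -486.9], [244.4, -481.4], [278.3, -475.9], [312.3, -470.3], [346.5, -464.7], [381.0, -459.2], [416.0, -453.6], [451.5, -447.9], [487.7, -442.1], [524.5, -436.1], [562.0, -429.8], [600.3, -423.0], [639.1, -415.7], [678.4, -407.7], [718.1, -399.0], [758.0, -389.2], [797.7, -378.5], [837.1, -366.6], [875.8, -353.5], [913.6, -339.1], [950.0, -323.4], [984.8, -306.4], [1017.5, -288.0], [1047.9, -268.4], [1075.6, -247.5], [1100.4, -225.5], [1122.0, -202.5], [1140.1, -178.6], [1154.8, -154.0], [1165.7, -128.8], [1173.0, -103.2], [1176.5, -77.4], [1176.4, -51.4], [1172.8, -25.6], [1165.8, 0.0]]]}}, {"type": "Feature", "properties": {"role": "start"}, "geometry": {"type": "Point", "coordinates": [-1100.4, 225.5]}}, {"type": "Feature", "properties": {"role": "capture_center"}, "geometry": {"type": "Point", "coordinates": [1122.0, -202.5]}}]}
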