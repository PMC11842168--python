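{"type": "FeatureCollection", "metadata": {"lake": "Lomond", "synthetic": true, "approximate": true, "note": "constructed stand-in shoreline; coarse aspect only, area normalized on load", "crs": "planar meters, centroid origin"}, "features": [{"type": "Feature", "properties": {"role": "lake"}, "geometry": {"type": "Polygon", "coordinates": [[[2908.3, 0.0], [2857.0, 280.9], [2802.0, 555.8], [2743.8, 824.4], [2683.0, 1086.3], [2620.1, 1341.5], [2555.6, 1590.0], [2490.1, 1832.0], [2423.8, 2067.7], [2357.1, 2297.8], [2290.4, 2522.6], [2224.0, 2743.0], [2157.9, 2959.5], [2092.3, 3173.1], [2027.2, 3384.6], [1962.8, 3594.7], [1898.8, 3804.2], [1835.2, 4013.9], [1771.9, 4224.5], [1708.6, 4436.4], [1645.0, 4650.1], [1581.0, 4866.0], [1516.3, 5084.0], [1450.5, 5304.1], [1383.4, 5526.1], [1314.7, 5749.4], [1244.1, 5973.6], [1171.5, 6197.6], [1096.5, 6420.4], [1019.1, 6640.9], [939.1, 6857.7], [856.4, 7069.2], [771.0, 7273.8], [682.9, 7469.9], [592.2, 7655.6], [499.0, 7829.1], [403.3, 7988.7], [305.3, 8132.7], [205.3, 8259.2], [103.5, 8366.8], [0.0, 8453.9], [-104.8, 8519.4], [-210.7, 8562.2], [-317.4, 8581.2], [-424.5, 8576.0], [-531.9, 8546.1], [-639.0, 8491.3], [-745.6, 8411.8], [-851.3, 8307.9], [-955.8, 8180.2], [-1058.6, 8029.6], [-1159.5, 7857.1], [-1257.9, 7664.0], [-1353.6, 7451.8], [-1446.2, 7222.2], [-1535.3, 6976.7], [-1620.6, 6717.4], [-1701.9, 6446.0], [-1778.9, 6164.5], [-1851.4, 5874.9], [-1919.2, 5579.0], [-1982.5, 5278.7], [-2041.0, 4975.6], [-2094.9, 4671.3], [-2144.4, 4367.4], [-2189.5, 4065.0], [-2230.7, 3765.2], [-2268.1, 3469.0], [-2302.2, 3177.0], [-2333.3, 2889.7], [-2361.9, 2607.4], [-2388.3, 2330.2], [-2412.9, 2057.9], [-2436.2, 1790.3], [-2458.5, 1527.0], [-2480.2, 1267.3], [-2501.4, 1010.8], [-2522.5, 756.6], [-2543.5, 503.9], [-2564.6, 252.0], [-2585.8, 0.0], [-2606.9, -252.8], [-2627.8, -507.0], [-2648.2, -763.4], [-2668.0, -1022.4], [-2686.5, -1284.4], [-2703.6, -1549.7], [-2718.6, -1818.3], [-2731.0, -2090.3], [-2740.2, -2365.3], [-2745.7, -2643.0], [-2746.8, -2922.8], [-2743.0, -3204.1], [-2733.7, -3486.0], [-2718.2, -3767.6], [-2696.2, -4047.9], [-2667.1, -4325.6], [-2630.5, -4599.6], [-2586.1, -4868.6], [-2533.7, -5131.5], [-2473.2, -5386.9], [-2404.4, -5633.6], [-2327.4, -5870.5], [-2242.3, -6096.5], [-2149.4, -6310.6], [-2049.0, -6511.9], [-1941.4, -6699.6], [-1827.2, -6873.0], [-1706.8, -7031.8], [-1580.8, -7175.5], [-1449.8, -7303.8], [-1314.5, -7416.8], [-1175.5, -7514.5], [-1033.4, -7596.9], [-888.8, -7664.5], [-742.3, -7717.5], [-594.6, -7756.4], [-446.0, -7781.7], [-297.1, -7793.9], [-148.3, -7793.7], [-0.0, -7781.6], [147.5, -7758.2], [294.0, -7724.0], [439.2, -7679.5], [582.8, -7625.1], [724.8, -7561.3], [865.0, -7488.3], [1003.3, -7406.3], [1139.4, -7315.6], [1273.4, -7216.2], [1404.9, -7108.0], [1533.9, -6991.1], [1660.2, -6865.2], [1783.6, -6730.3], [1903.8, -6586.1], [2020.4, -6432.4], [2133.3, -6269.0], [2242.0, -6095.6], [2346.1, -5912.2], [2445.3, -5718.5], [2539.2, -5514.6], [2627.3, -5300.3], [2709.2, -5076.0], [2784.5, -4841.6], [2852.9, -4597.7], [2914.0, -4344.5], [2967.5, -4082.6], [3013.1, -3812.6], [3050.7, -3535.4], [3080.2, -3251.7], [3101.6, -2962.5], [3114.8, -2668.7], [3119.9, -2371.5], [3117.2, -2071.9], [3107.0, -1771.1], [3089.5, -1470.2], [3065.1, -1170.2], [3034.3, -872.3], [2997.5, -577.3], [2955.3, -286.3], [2908.3, 0.0]]]}}, {"type": "Feature", "properties": {"role": "start"}, "geometry": {"type": "Point", "coordinates": [2627.3, -5300.3]}}, {"type": "Feature", "properties": {"role": "capture_center"}, "geometry": {"type": "Point", "coordinates": [-2533.7, -5131.5]}}]}
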