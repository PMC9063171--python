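index,unit_system,slope,intercept,r2,rmse
Area,original-pixel,0.6876076,-14.13069,0.7639,1.39916
Area,enhanced-pixel,0.007242,-11.96377,0.8197,1.22279
Area,SI,3.4546529,-10.50562,0.8197,1.22279
Minor,original-pixel,11.473872,-40.04071,0.7726,1.37308
Minor,enhanced-pixel,1.206266,-38.92239,0.8478,1.12329
Minor,SI,26.223532,-37.43548,0.8501,1.11472
MinFeret,original-pixel,11.479164,-47.28420,0.7802,1.34983
MinFeret,enhanced-pixel,1.185451,-39.77784,0.8389,1.15583
MinFeret,SI,25.751014,-38.21530,0.8409,1.14849
Area/Perim.,original-pixel,43.088447,-56.75704,0.7957,1.30144
Area/Perim.,enhanced-pixel,4.580449,-53.57889,0.8763,1.01287
Area/Perim.,SI,98.930057,-51.22634,0.8759,1.01427
Area x Circ.,original-pixel,0.7810103,-9.19948,0.7958,1.30124
Area x Circ.,enhanced-pixel,0.009157,-7.648741,0.8786,1.00327
Area x Circ.,SI,4.3865946,-6.502854,0.8784,1.00403
Minor/Solidity,original-pixel,11.300208,-47.78814,0.7856,1.33331
Minor/Solidity,enhanced-pixel,1.189310,-40.20437,0.8371,1.16220
Minor/Solidity,SI,25.845173,-38.66377,0.8396,1.15317
MinF/Solidity,original-pixel,11.243958,-55.24627,0.7836,1.33950
MinF/Solidity,enhanced-pixel,1.166277,-40.90504,0.8259,1.20137
MinF/Solidity,SI,25.326662,-39.29586,0.8282,1.19332
Area x Solidity,original-pixel,0.7367298,-12.03813,0.7702,1.38042
Area x Solidity,enhanced-pixel,0.007417,-11.62672,0.8298,1.18779
Area x Solidity,SI,3.5390870,-10.18897,0.8295,1.18879
Perim. x Circ.,original-pixel,3.3790373,-54.79264,0.7925,1.31155
Perim. x Circ.,enhanced-pixel,0.359924,-51.66935,0.8765,1.01190
Perim. x Circ.,SI,7.7804528,-49.44107,0.8764,1.01215
A1,original-pixel,0.0017579,13.56291,0.7996,1.28896
A1,enhanced-pixel,2.1504e-07,14.393318,0.8691,1.04158
A1,SI,0.0505571,15.011033,0.8685,1.04405
A2,original-pixel,0.0018807,14.06366,0.8003,1.28685
A2,enhanced-pixel,2.2128e-07,14.390431,0.8748,1.01874
A2,SI,0.0520301,15.005713,0.8742,1.02147
Kim index,original-pixel,0.1306980,-1.60504,0.7644,1.39762
Kim index,enhanced-pixel,0.000325,0.0399900,0.8200,1.22159
Kim index,SI,1.1264207,1.1437907,0.8200,1.22156
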