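region,country,n,tropacocaine_mean,tropacocaine_sd,trimethoxycocaine_mean,trimethoxycocaine_sd,truxillines_mean,truxillines_sd,d15N_mean,d15N_sd,d13C_mean,d13C_sd,d2H_mean,d2H_sd,d18O_mean,d18O_sd
Amazonas,Colombia,19,0.41,0.17,0.69,0.20,3.9,0.6,-4.3,0.9,-35.7,0.5,-210.9,10.0,12.9,1.9
Antioquia,Colombia,20,0.61,0.31,0.26,0.09,6.2,1.3,-7.6,1.5,-34.3,0.4,-228.7,4.7,10.4,1.1
Arauca,Colombia,20,4.86,2.72,0.01,0.00,24.1,9.7,-7.4,2.2,-33.4,0.5,-167.8,7.0,23.8,2.1
Caquetá,Colombia,30,0.48,0.56,0.30,0.34,9.7,5.1,-0.9,2.0,-34.3,0.4,-189.0,17.8,18.6,3.1
Cauca,Colombia,12,1.28,2.01,0.24,0.19,7.4,5.0,-6.0,2.3,-33.3,1.3,-199.0,9.0,16.3,1.8
Chapare,Bolivia,56,0.26,0.06,0.16,0.03,2.7,0.3,-12.3,1.2,-34.5,0.3,-220.1,15.2,15.1,3.0
Chocó,Colombia,20,0.75,0.45,0.50,0.14,3.5,0.8,-8.8,0.6,-34.9,0.5,-218.5,3.9,11.3,2.5
Cusco,Peru,41,0.12,0.04,0.27,0.06,4.1,1.6,-9.5,0.8,-33.7,0.4,-226.7,14.1,18.3,3.4
Guaviare,Colombia,18,0.14,0.11,0.59,0.19,4.3,1.5,-5.2,1.4,-34.9,0.6,-191.9,7.6,19.2,2.1
Meta,Colombia,19,0.73,0.49,0.73,0.24,5.0,1.4,-5.5,1.7,-34.8,0.4,-223.6,7.1,12.0,1.8
Nariño,Colombia,33,0.53,0.41,0.47,0.30,4.2,3.3,-8.8,1.7,-35.5,0.8,-199.1,5.1,16.1,1.8
Norte de Santander,Colombia,15,3.52,4.39,0.35,0.37,26.4,24.7,-4.0,1.8,-34.4,1.0,-207.5,4.6,14.4,1.1
Putumayo,Colombia,36,0.75,1.19,0.60,0.21,7.6,3.4,-4.5,2.0,-34.4,0.7,-205.6,9.0,18.7,2.1
San Lucas,Colombia,20,2.40,1.75,0.04,0.11,22.2,5.4,-4.8,2.3,-33.7,0.6,-181.2,7.1,19.5,1.6
Santander,Colombia,18,0.51,0.30,0.62,0.39,4.7,2.7,-9.1,1.3,-35.2,0.6,-197.2,9.8,15.5,1.5
UHV,Peru,96,0.17,0.06,0.19,0.04,3.7,0.6,-8.1,1.1,-35.0,0.4,-219.0,11.1,15.1,2.6
Valle de Cauca,Colombia,19,1.00,0.45,0.19,0.04,4.1,0.7,-10.1,1.4,-34.7,0.4,-225.0,2.4,12.2,0.9
Vaupés,Colombia,18,0.56,0.32,0.50,0.18,4.7,1.1,-6.8,1.9,-35.7,0.6,-194.2,5.7,17.5,1.4
Vichada,Colombia,19,1.06,0.07,1.77,0.45,6.7,0.4,-4.7,0.2,-35.6,0.1,-209.1,5.0,13.4,0.3
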