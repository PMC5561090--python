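year,ca_ppm,d13c_air_permil
1500,280.0,-6.4
1501,280.0,-6.4
1502,280.0,-6.4
1503,280.0,-6.4
1504,280.0,-6.4
1505,280.0,-6.4
1506,280.0,-6.4
1507,280.0,-6.4
1508,280.0,-6.4
1509,280.0,-6.4
1510,280.0,-6.4
1511,280.0,-6.4
1512,280.0,-6.4
1513,280.0,-6.4
1514,280.0,-6.4
1515,280.0,-6.4
1516,280.0,-6.4
1517,280.0,-6.4
1518,280.0,-6.4
1519,280.0,-6.4
1520,280.0,-6.4
1521,280.0,-6.4
1522,280.0,-6.4
1523,280.0,-6.4
1524,280.0,-6.4
1525,280.0,-6.4
1526,280.0,-6.4
1527,280.0,-6.4
1528,280.0,-6.4
1529,280.0,-6.4
1530,280.0,-6.4
1531,280.0,-6.4
1532,280.0,-6.4
1533,280.0,-6.4
1534,280.0,-6.4
1535,280.0,-6.4
1536,280.0,-6.4
1537,280.0,-6.4
1538,280.0,-6.4
1539,280.0,-6.4
1540,280.0,-6.4
1541,280.0,-6.4
1542,280.0,-6.4
1543,280.0,-6.4
1544,280.0,-6.4
1545,280.0,-6.4
1546,280.0,-6.4
1547,280.0,-6.4
1548,280.0,-6.4
1549,280.0,-6.4
1550,280.0,-6.4
1551,280.0,-6.4
1552,280.0,-6.4
1553,280.0,-6.4
1554,280.0,-6.4
1555,280.0,-6.4
1556,280.0,-6.4
1557,280.0,-6.4
1558,280.0,-6.4
1559,280.0,-6.4
1560,280.0,-6.4
1561,280.0,-6.4
1562,280.0,-6.4
1563,280.0,-6.4
1564,280.0,-6.4
1565,280.0,-6.4
1566,280.0,-6.4
1567,280.0,-6.4
1568,280.0,-6.4
1569,280.0,-6.4
1570,280.0,-6.4
1571,280.0,-6.4
1572,280.0,-6.4
1573,280.0,-6.4
1574,280.0,-6.4
1575,280.0,-6.4
1576,280.0,-6.4
1577,280.0,-6.4
1578,280.0,-6.4
1579,280.0,-6.4
1580,280.0,-6.4
1581,280.0,-6.4
1582,280.0,-6.4
1583,280.0,-6.4
1584,280.0,-6.4
1585,280.0,-6.4
1586,280.0,-6.4
1587,280.0,-6.4
1588,280.0,-6.4
1589,280.0,-6.4
1590,280.0,-6.4
1591,280.0,-6.4
1592,280.0,-6.4
1593,280.0,-6.4
1594,280.0,-6.4
1595,280.0,-6.4
1596,280.0,-6.4
1597,280.0,-6.4
1598,280.0,-6.4
1599,280.0,-6.4
1600,280.0,-6.4
1601,280.0,-6.4
1602,280.0,-6.4
1603,280.0,-6.4
1604,280.0,-6.4
1605,280.0,-6.4
1606,280.0,-6.4
1607,280.0,-6.4
1608,280.0,-6.4
1609,280.0,-6.4
1610,280.0,-6.4
1611,280.0,-6.4
1612,280.0,-6.4
1613,280.0,-6.4
1614,280.0,-6.4
1615,280.0,-6.4
1616,280.0,-6.4
1617,280.0,-6.4
1618,280.0,-6.4
1619,280.0,-6.4
1620,280.0,-6.4
1621,280.0,-6.4
1622,280.0,-6.4
1623,280.0,-6.4
1624,280.0,-6.4
1625,280.0,-6.4
1626,280.0,-6.4
1627,280.0,-6.4
1628,280.0,-6.4
1629,280.0,-6.4
1630,280.0,-6.4
1631,280.0,-6.4
1632,280.0,-6.4
1633,280.0,-6.4
1634,280.0,-6.4
1635,280.0,-6.4
1636,280.0,-6.4
1637,280.0,-6.4
1638,280.0,-6.4
1639,280.0,-6.4
1640,280.0,-6.4
1641,280.0,-6.4
1642,280.0,-6.4
1643,280.0,-6.4
1644,280.0,-6.4
1645,280.0,-6.4
1646,280.0,-6.4
1647,280.0,-6.4
1648,280.0,-6.4
1649,280.0,-6.4
1650,280.0,-6.4
1651,280.0,-6.4
1652,280.0,-6.4
1653,280.0,-6.4
1654,280.0,-6.4
1655,280.0,-6.4
1656,280.0,-6.4
1657,280.0,-6.4
1658,280.0,-6.4
1659,280.0,-6.4
1660,280.0,-6.4
1661,280.0,-6.4
1662,280.0,-6.4
1663,280.0,-6.4
1664,280.0,-6.4
1665,280.0,-6.4
1666,280.0,-6.4
1667,280.0,-6.4
1668,280.0,-6.4
1669,280.0,-6.4
1670,280.0,-6.4
1671,280.0,-6.4
1672,280.0,-6.4
1673,280.0,-6.4
1674,280.0,-6.4
1675,280.0,-6.4
1676,280.0,-6.4
1677,280.0,-6.4
1678,280.0,-6.4
1679,280.0,-6.4
1680,280.0,-6.4
1681,280.0,-6.4
1682,280.0,-6.4
1683,280.0,-6.4
1684,280.0,-6.4
1685,280.0,-6.4
1686,280.0,-6.4
1687,280.0,-6.4
1688,280.0,-6.4
1689,280.0,-6.4
1690,280.0,-6.4
1691,280.0,-6.4
1692,280.0,-6.4
1693,280.0,-6.4
1694,280.0,-6.4
1695,280.0,-6.4
1696,280.0,-6.4
1697,280.0,-6.4
1698,280.0,-6.4
1699,280.0,-6.4
1700,280.0,-6.4
1701,280.0,-6.4
1702,280.0,-6.4
1703,280.0,-6.4
1704,280.0,-6.4
1705,280.0,-6.4
1706,280.0,-6.4
1707,280.0,-6.4
1708,280.0,-6.4
1709,280.0,-6.4
1710,280.0,-6.4
1711,280.0,-6.4
1712,280.0,-6.4
1713,280.0,-6.4
1714,280.0,-6.4
1715,280.0,-6.4
1716,280.0,-6.4
1717,280.0,-6.4
1718,280.0,-6.4
1719,280.0,-6.4
1720,280.0,-6.4
1721,280.0,-6.4
1722,280.0,-6.4
1723,280.0,-6.4
1724,280.0,-6.4
1725,280.0,-6.4
1726,280.0,-6.4
1727,280.0,-6.4
1728,280.0,-6.4
1729,280.0,-6.4
1730,280.0,-6.4
1731,280.0,-6.4
1732,280.0,-6.4
1733,280.0,-6.4
1734,280.0,-6.4
1735,280.0,-6.4
1736,280.0,-6.4
1737,280.0,-6.4
1738,280.0,-6.4
1739,280.0,-6.4
1740,280.0,-6.4
1741,280.0,-6.4
1742,280.0,-6.4
1743,280.0,-6.4
1744,280.0,-6.4
1745,280.0,-6.4
1746,280.0,-6.4
1747,280.0,-6.4
1748,280.0,-6.4
1749,280.0,-6.4
1750,280.0,-6.4
1751,280.0,-6.4
1752,280.0,-6.4
1753,280.0,-6.4
1754,280.0,-6.4
1755,280.0,-6.4
1756,280.0,-6.4
1757,280.0,-6.4
1758,280.0,-6.4
1759,280.0,-6.4
1760,280.0,-6.4
1761,280.0,-6.4
1762,280.0,-6.4
1763,280.0,-6.4
1764,280.0,-6.4
1765,280.0,-6.4
1766,280.0,-6.4
1767,280.0,-6.4
1768,280.0,-6.4
1769,280.0,-6.4
1770,280.0,-6.4
1771,280.0,-6.4
1772,280.0,-6.4
1773,280.0,-6.4
1774,280.0,-6.4
1775,280.0,-6.4
1776,280.0,-6.4
1777,280.0,-6.4
1778,280.0,-6.4
1779,280.0,-6.4
1780,280.0,-6.4
1781,280.0,-6.4
1782,280.0,-6.4
1783,280.0,-6.4
1784,280.0,-6.4
1785,280.0,-6.4
1786,280.0,-6.4
1787,280.0,-6.4
1788,280.0,-6.4
1789,280.0,-6.4
1790,280.0,-6.4
1791,280.0,-6.4
1792,280.0,-6.4
1793,280.0,-6.4
1794,280.0,-6.4
1795,280.0,-6.4
1796,280.0,-6.4
1797,280.0,-6.4
1798,280.0,-6.4
1799,280.0,-6.4
1800,280.0,-6.4
1801,280.0,-6.4
1802,280.0,-6.4
1803,280.0,-6.4
1804,280.0,-6.4
1805,280.0,-6.4
1806,280.0,-6.4
1807,280.0,-6.4
1808,280.0,-6.4
1809,280.0,-6.4
1810,280.0,-6.4
1811,280.0,-6.4
1812,280.0,-6.4
1813,280.0,-6.4
1814,280.0,-6.4
1815,280.0,-6.4
1816,280.0,-6.4
1817,280.0,-6.4
1818,280.0,-6.4
1819,280.0,-6.4
1820,280.0,-6.4
1821,280.0,-6.4
1822,280.0,-6.4
1823,280.0,-6.4
1824,280.0,-6.4
1825,280.0,-6.4
1826,280.0,-6.4
1827,280.0,-6.4
1828,280.0,-6.4
1829,280.0,-6.4
1830,280.0,-6.4
1831,280.0,-6.4
1832,280.0,-6.4
1833,280.0,-6.4
1834,280.0,-6.4
1835,280.0,-6.4
1836,280.0,-6.4
1837,280.0,-6.4
1838,280.0,-6.4
1839,280.0,-6.4
1840,280.0,-6.4
1841,280.0,-6.4
1842,280.0,-6.4
1843,280.0,-6.4
1844,280.0,-6.4
1845,280.0,-6.4
1846,280.0,-6.4
1847,280.0,-6.4
1848,280.0,-6.4
1849,280.0,-6.4
1850,280.0,-6.4
1851,280.0,-6.4
1852,280.0,-6.4
1853,280.0,-6.4
1854,280.0,-6.4
1855,280.0,-6.4
1856,280.0,-6.4
1857,280.0,-6.4
1858,280.0,-6.4
1859,280.0,-6.4
1860,280.0,-6.4
1861,280.0,-6.4
1862,280.0,-6.4
1863,280.0,-6.4
1864,280.0,-6.4
1865,280.0,-6.4
1866,280.0,-6.4
1867,280.0,-6.4
1868,280.0,-6.4
1869,280.0,-6.4
1870,280.0,-6.4
1871,280.0,-6.4
1872,280.0,-6.4
1873,280.0,-6.4
1874,280.0,-6.4
1875,280.0,-6.4
1876,280.0,-6.4
1877,280.0,-6.4
1878,280.0,-6.4
1879,280.0,-6.4
1880,280.0,-6.4
1881,280.0,-6.4
1882,280.0,-6.4
1883,280.0,-6.4
1884,280.0,-6.4
1885,280.0,-6.4
1886,280.0,-6.4
1887,280.0,-6.4
1888,280.0,-6.4
1889,280.0,-6.4
1890,280.0,-6.4
1891,280.0,-6.4
1892,280.0,-6.4
1893,280.0,-6.4
1894,280.0,-6.4
1895,280.0,-6.4
1896,280.0,-6.4
1897,280.0,-6.4
1898,280.0,-6.4
1899,280.0,-6.4
1900,280.0,-6.4
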